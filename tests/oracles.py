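"""Independent brute-force oracles used to validate the fast implementations.

Everything here works per-base, per-subset or per-permutation — slow but
obviously correct — and shares no code with the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# Per-base super-enhancer calling (exclude -> stitch -> score -> cut)
# ---------------------------------------------------------------------------

def bf_exclude(peaks: list[tuple[int, int]], tsses: list[int], pad: int,
               genome_length: int) -> list[tuple[int, int]]:
    """Per-base TSS exclusion; returns remaining peak fragments."""
    masked = np.zeros(genome_length, dtype=bool)
    for tss in tsses:
        masked[max(0, tss - pad): tss + pad + 1] = True
    out = []
    for start, end in peaks:
        keep = np.flatnonzero(~masked[start:end]) + start
        if len(keep) == 0:
            continue
        run_start = keep[0]
        prev = keep[0]
        for pos in keep[1:]:
            if pos != prev + 1:
                out.append((int(run_start), int(prev) + 1))
                run_start = pos
            prev = pos
        out.append((int(run_start), int(prev) + 1))
    return out


def bf_stitch(peaks: list[tuple[int, int]], distance: int) -> list[tuple[int, int]]:
    """O(n^2) union-find stitching."""
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = peaks[i], peaks[j]
            gap = max(s1, s2) - min(e1, e2)
            if gap <= distance:
                parent[find(i)] = find(j)
    groups: dict[int, list[tuple[int, int]]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(peaks[i])
    return sorted(
        (min(s for s, _ in g), max(e for _, e in g)) for g in groups.values()
    )


def bf_area(track_per_base: np.ndarray, start: int, end: int) -> float:
    return float(track_per_base[start:end].sum())


def bf_inflection_count(net_desc: list[float]) -> int:
    """Diagonal-tangent scan over every rank position of the rescaled
    ascending curve: the cutoff is the last point with the smallest
    vertical distance below the unit-slope diagonal."""
    n = len(net_desc)
    if n < 3:
        return 0
    asc = sorted(net_desc)
    lo, hi = asc[0], asc[-1]
    if hi == lo:
        return 0
    best, cut_idx = None, None
    for i in range(n):
        d = (asc[i] - lo) / (hi - lo) - i / (n - 1)
        if best is None or d <= best:
            best, cut_idx = d, i
    cutoff = asc[cut_idx]
    return sum(v > cutoff for v in net_desc)


def bf_call_se(peaks, tsses, chip_per_base, input_per_base, pad, distance):
    """Full brute-force SE call.

    Returns list of (start, end, net, is_se) sorted by rank (net desc, width
    desc, start asc).
    """
    genome_length = len(chip_per_base)
    kept = bf_exclude(peaks, tsses, pad, genome_length)
    if not kept:
        return []
    regions = bf_stitch(kept, distance)
    scored = []
    for start, end in regions:
        net = max(bf_area(chip_per_base, start, end)
                  - bf_area(input_per_base, start, end), 0.0)
        scored.append([start, end, net])
    scored.sort(key=lambda r: (-r[2], -(r[1] - r[0]), r[0]))
    n_se = bf_inflection_count([r[2] for r in scored])
    return [(s, e, net, rank < n_se) for rank, (s, e, net) in enumerate(scored)]


# ---------------------------------------------------------------------------
# Maximal cliques by subset enumeration
# ---------------------------------------------------------------------------

def bf_max_cliques(nodes: list[str], mutual_edges: set[frozenset]) -> set[frozenset]:
    """All maximal cliques of the mutual graph by 2^n enumeration."""
    idx = {n: i for i, n in enumerate(nodes)}
    adj = [0] * len(nodes)
    for e in mutual_edges:
        a, b = tuple(e)
        adj[idx[a]] |= 1 << idx[b]
        adj[idx[b]] |= 1 << idx[a]
    for i in range(len(nodes)):
        adj[i] |= 1 << i
    cliques = []
    for mask in range(1, 1 << len(nodes)):
        is_clique = all(
            (adj[i] & mask) == mask
            for i in range(len(nodes)) if mask >> i & 1
        )
        if is_clique:
            cliques.append(mask)
    maximal = set()
    for c in cliques:
        if not any(c != d and (c & d) == c for d in cliques):
            maximal.add(frozenset(nodes[i] for i in range(len(nodes)) if c >> i & 1))
    return maximal


# ---------------------------------------------------------------------------
# Motif scan
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def bf_scan(sequence: str, matrix: np.ndarray, pseudocount: float,
            threshold: float) -> list[tuple[int, str, float]]:
    """Per-offset both-strand log-odds scan; (offset, strand, score)."""
    bg = 0.25
    order = "ACGT"
    m = len(matrix)
    hits = []
    for strand in "+-":
        if strand == "+":
            seq = sequence
        else:
            seq = "".join(_COMP[b] for b in reversed(sequence))
        for o in range(len(seq) - m + 1):
            score = 0.0
            for k in range(m):
                base = seq[o + k]
                if base == "N":
                    continue
                p = matrix[k][order.index(base)]
                score += math.log2((p + pseudocount * bg) / ((1 + pseudocount) * bg))
            if score >= threshold:
                fwd_offset = o if strand == "+" else len(seq) - m - o
                hits.append((fwd_offset, strand, score))
    return sorted(hits)


# ---------------------------------------------------------------------------
# Exact rank tests by enumeration
# ---------------------------------------------------------------------------

def _mwu_u(a, b):
    return sum(1.0 for x in a for y in b if x > y) + \
        0.5 * sum(1.0 for x in a for y in b if x == y)


def bf_mannwhitney_p(a, b, alternative):
    """Exact Mann–Whitney p by enumerating all group assignments.

    Uses the rank-sum identity U = W − n_a(n_a+1)/2 (valid with midranks)
    so each assignment costs O(n_a).
    """
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    n = len(a)
    ranks = _midranks(pooled)
    offset = n * (n + 1) / 2.0
    u_obs = _mwu_u(a, b)
    us = np.array([ranks[list(sel)].sum() - offset
                   for sel in itertools.combinations(range(len(pooled)), n)])
    assert abs((ranks[:n].sum() - offset) - u_obs) < 1e-9  # identity check
    p_less = np.mean(us <= u_obs + 1e-12)
    p_greater = np.mean(us >= u_obs - 1e-12)
    if alternative == "less":
        return float(p_less)
    if alternative == "greater":
        return float(p_greater)
    return float(min(1.0, 2 * min(p_less, p_greater)))


def bf_signed_rank_p(a, b, alternative):
    """Exact Wilcoxon signed-rank p by enumerating 2^n sign patterns."""
    diffs = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    ranks = _midranks(np.abs(diffs))
    w_obs = float(ranks[diffs > 0].sum())
    ws = []
    for signs in itertools.product([1, -1], repeat=n):
        signs = np.array(signs)
        ws.append(float(ranks[signs > 0].sum()))
    ws = np.array(ws)
    p_greater = np.mean(ws >= w_obs)
    p_less = np.mean(ws <= w_obs)
    if alternative == "greater":
        return float(p_greater)
    if alternative == "less":
        return float(p_less)
    return float(min(1.0, 2 * min(p_less, p_greater)))


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values)
    ranks = np.empty(len(values))
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks
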