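"""Core transcriptional regulatory circuitry (CRC) inference.

A CRC is a set of super-enhancer-associated, auto-regulated transcription
factors whose binding motifs occur in each other's SEs, forming fully
interconnected feed-forward loops.  The module scans SE sequences with
position weight matrices (log-odds against a background model, both
strands), builds the directed TF→TF motif-support graph, enumerates
maximal cliques over the mutual edges, and ranks TFs by clique
participation, co-expression and SE rank.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PWM",
    "MotifHit",
    "CRCGraph",
    "TFScore",
    "read_jaspar",
    "write_jaspar",
    "read_meme",
    "scan_motifs",
    "build_crc_graph",
    "crc_from_sequences",
    "enumerate_cliques",
    "clique_scores",
    "coexpression",
    "rank_core_tfs",
]

_ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate(_ALPHABET)}
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities over ACGT."""

    name: str
    matrix: np.ndarray                      # (length, 4) probabilities
    pseudocount: float = 0.01
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if len(self.matrix) < 4:
            raise ValueError("PWM length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM columns must each sum to 1")

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def log_odds(self) -> np.ndarray:
        """(length, 5) log2-odds; column 5 is N, scoring as background (0)."""
        bg = self.background
        with np.errstate(divide="ignore"):  # -inf is fine for pseudocount 0
            lo = np.log2((self.matrix + self.pseudocount * bg) /
                         ((1.0 + self.pseudocount) * bg))
        return np.hstack([lo, np.zeros((len(lo), 1))])

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    """One above-threshold PWM match inside a scanned region."""

    tf: str
    region: str            # region identifier (e.g. "chrS:100-900")
    offset: int            # offset of the match within the region
    strand: str            # "+" or "-"
    score: float           # log-odds score in bits


# ---------------------------------------------------------------------------
# Motif file formats
# ---------------------------------------------------------------------------

def read_jaspar(path: str | Path) -> list[PWM]:
    """Read JASPAR-style PFMs (counts or probabilities → probabilities).

    Accepts both the bracketed ``A [ 1 2 3 ]`` row style and plain 4-row
    matrices under each ``>`` header.
    """
    pwms: list[PWM] = []
    name = None
    rows: dict[str, list[float]] = {}
    order: list[str] = []

    def _flush():
        nonlocal rows, order
        if name is None:
            return
        if set(rows) == set(_ALPHABET):
            mat = np.array([rows[b] for b in _ALPHABET], dtype=float).T
        elif len(order) == 4 and not rows:
            raise ValueError(f"motif {name}: no rows parsed")
        else:
            raise ValueError(f"motif {name}: expected rows for A, C, G, T")
        col_sums = mat.sum(axis=1, keepdims=True)
        if np.any(col_sums <= 0):
            raise ValueError(f"motif {name}: zero column sum")
        pwms.append(PWM(name=name, matrix=mat / col_sums))
        rows, order = {}, []

    plain_rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if plain_rows:
                    for b, vals in zip(_ALPHABET, plain_rows):
                        rows[b] = vals
                    plain_rows = []
                _flush()
                name = line[1:].split()[0] if line[1:].split() else "motif"
                parts = line[1:].split()
                if len(parts) > 1:
                    name = parts[1]  # prefer TF name over matrix id
                continue
            m = re.match(r"^([ACGT])\s*\[?\s*([-\d.\seE+]+?)\s*\]?\s*$", line)
            if m:
                rows[m.group(1)] = [float(x) for x in m.group(2).split()]
            else:
                plain_rows.append([float(x) for x in line.split()])
    if plain_rows:
        for b, vals in zip(_ALPHABET, plain_rows):
            rows[b] = vals
    _flush()
    return pwms


def write_jaspar(pwms: Sequence[PWM], path: str | Path,
                 counts_scale: int = 100) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name} {pwm.name}\n")
            counts = np.round(pwm.matrix * counts_scale).astype(int)
            for bi, b in enumerate(_ALPHABET):
                vals = " ".join(str(v) for v in counts[:, bi])
                fh.write(f"{b} [ {vals} ]\n")


def read_meme(path: str | Path) -> list[PWM]:
    """Read MEME minimal-format motifs (letter-probability matrices)."""
    pwms: list[PWM] = []
    name = None
    collecting = False
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                parts = line.split()
                name = parts[-1] if len(parts) > 2 else parts[1]
                collecting = False
                rows = []
            elif line.startswith("letter-probability"):
                collecting = True
            elif collecting:
                if line and line[0].isdigit() or line.startswith(("0", "1", ".")):
                    rows.append([float(x) for x in line.split()])
                else:
                    if rows and name:
                        pwms.append(PWM(name=name, matrix=np.array(rows)))
                    collecting = False
    if collecting and rows and name:
        pwms.append(PWM(name=name, matrix=np.array(rows)))
    return pwms


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(len(arr), 4, dtype=np.int64)  # default N
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    return codes


def _strand_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    m = len(lo)
    n = len(codes) - m + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for k in range(m):
        scores += lo[k, codes[k: k + n]]
    return scores


def scan_motifs(sequence: str, pwm: PWM, threshold: float | None = None,
                region: str = "region") -> list[MotifHit]:
    """All both-strand PWM matches scoring ≥ ``threshold`` bits.

    ``threshold`` defaults to 80% of the PWM's maximum attainable score.
    Reverse-strand hits are reported at the offset of the match's leftmost
    base on the forward sequence.  Ns contribute 0 (background).
    """
    if threshold is None:
        threshold = 0.8 * pwm.max_score
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    m = len(pwm)
    if m > len(sequence):
        return []
    lo = pwm.log_odds
    fwd_codes = _encode(sequence)
    hits: list[MotifHit] = []
    fwd = _strand_scores(fwd_codes, lo)
    for o in np.flatnonzero(fwd >= threshold):
        hits.append(MotifHit(pwm.name, region, int(o), "+", float(fwd[o])))
    rev_codes = _encode(_revcomp(sequence))
    rev = _strand_scores(rev_codes, lo)
    L = len(sequence)
    for o in np.flatnonzero(rev >= threshold):
        # offset o on the revcomp maps to forward offset L - m - o
        hits.append(MotifHit(pwm.name, region, int(L - m - o), "-", float(rev[o])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Graph, cliques, scores
# ---------------------------------------------------------------------------

@dataclass
class CRCGraph:
    """Directed TF→TF motif-support graph over auto-regulated SE TFs."""

    graph: nx.DiGraph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def edge_count(self, a: str, b: str) -> int:
        return self.graph.edges[a, b]["hits"] if self.graph.has_edge(a, b) else 0

    def mutual_graph(self) -> nx.Graph:
        """Undirected graph of mutual (i→j and j→i) edges, self-loops dropped."""
        und = nx.Graph()
        und.add_nodes_from(self.graph.nodes)
        for a, b in self.graph.edges:
            if a != b and self.graph.has_edge(b, a):
                und.add_edge(a, b)
        return und


def build_crc_graph(se_assignments: Mapping[str, Sequence],
                    hit_counts: Mapping[tuple[str, str], int],
                    expressed_tfs: set[str] | None = None) -> CRCGraph:
    """Assemble the CRC graph from per-pair motif hit counts.

    ``se_assignments`` maps TF name → its SE regions (TFs without an SE are
    not candidates); ``hit_counts[(i, j)]`` is the number of motif hits of
    TF i inside any SE of TF j.  A TF is a node iff it is expressed, has an
    SE, and its own motif hits its own SE (auto-regulation).  Edges i→j are
    kept between nodes whenever ≥ 1 hit supports them.
    """
    candidates = [tf for tf, regions in se_assignments.items() if len(regions) > 0]
    if expressed_tfs is not None:
        candidates = [tf for tf in candidates if tf in expressed_tfs]
    nodes = [tf for tf in candidates if hit_counts.get((tf, tf), 0) >= 1]
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    node_set = set(nodes)
    for (a, b), count in hit_counts.items():
        if count >= 1 and a in node_set and b in node_set:
            g.add_edge(a, b, hits=int(count))
    if not nodes:
        warnings.warn("no auto-regulated SE-associated TFs; empty CRC graph",
                      stacklevel=2)
    return CRCGraph(graph=g)


def crc_from_sequences(se_sequences: Mapping[str, Sequence[tuple[str, str]]],
                       pwms: Mapping[str, PWM],
                       threshold_frac: float = 0.8,
                       expressed_tfs: set[str] | None = None
                       ) -> tuple[CRCGraph, dict[tuple[str, str], list[MotifHit]]]:
    """Scan every TF's PWM over every TF's SE sequences and build the graph.

    ``se_sequences`` maps TF → list of (region_id, sequence) for its SEs.
    Returns the graph and the per-(source, target) hit lists.
    """
    hits: dict[tuple[str, str], list[MotifHit]] = {}
    counts: dict[tuple[str, str], int] = {}
    for src, pwm in pwms.items():
        threshold = threshold_frac * pwm.max_score
        for dst, regions in se_sequences.items():
            found: list[MotifHit] = []
            for region_id, seq in regions:
                found.extend(scan_motifs(seq, pwm, threshold, region=region_id))
            if found:
                hits[(src, dst)] = found
                counts[(src, dst)] = len(found)
    graph = build_crc_graph(
        {tf: list(regions) for tf, regions in se_sequences.items()},
        counts, expressed_tfs=expressed_tfs,
    )
    return graph, hits


def enumerate_cliques(crc: CRCGraph, cap: int = 25) -> list[frozenset[str]]:
    """Maximal cliques over the mutual-edge graph (Bron–Kerbosch, pivoting).

    Singletons appear only when no larger clique contains the node.
    """
    und = crc.mutual_graph()
    if und.number_of_nodes() > cap:
        raise ValueError(
            f"{und.number_of_nodes()} nodes exceeds cap {cap}; filter TFs first"
        )
    cliques = [frozenset(c) for c in nx.find_cliques(und)]
    return sorted(cliques, key=lambda c: (-len(c), sorted(c)))


@dataclass
class TFScore:
    tf: str
    clique_fraction: float
    mean_coexpression: float
    se_rank: int


def clique_scores(cliques: Sequence[frozenset[str]],
                  tfs: Sequence[str]) -> dict[str, float]:
    """Fraction of maximal cliques containing each TF (NaN if no cliques)."""
    if len(cliques) == 0:
        warnings.warn("zero cliques; clique fractions undefined", stacklevel=2)
        return {tf: math.nan for tf in tfs}
    return {tf: sum(tf in c for c in cliques) / len(cliques) for tf in tfs}


def coexpression(expr: pd.DataFrame, tfs: Sequence[str]) -> pd.DataFrame:
    """Pairwise Pearson correlation of log2(FPKM + 1) across samples.

    Zero-variance TFs yield NaN off-diagonals (flagged); the diagonal is 1.
    """
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    missing = [tf for tf in tfs if tf not in expr.index]
    if missing:
        raise KeyError(f"TFs absent from expression matrix: {missing}")
    x = np.log2(expr.loc[list(tfs)].to_numpy(dtype=float) + 1.0)
    sd = x.std(axis=1)
    zero_var = sd == 0
    if np.any(zero_var):
        warnings.warn(
            f"zero-variance TFs: {[t for t, z in zip(tfs, zero_var) if z]}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr = np.atleast_2d(corr)
    corr = (corr + corr.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=list(tfs), columns=list(tfs))


def rank_core_tfs(scores: Sequence[TFScore]) -> list[TFScore]:
    """Order TFs by clique_fraction desc, co-expression desc, SE rank asc."""
    def _key(s: TFScore):
        cf = -math.inf if math.isnan(s.clique_fraction) else s.clique_fraction
        co = -math.inf if math.isnan(s.mean_coexpression) else s.mean_coexpression
        return (-cf, -co, s.se_rank, s.tf)

    return sorted(scores, key=_key)


def score_tfs(cliques: Sequence[frozenset[str]],
              coexpr: pd.DataFrame,
              se_ranks: Mapping[str, int],
              tfs: Sequence[str]) -> list[TFScore]:
    """Assemble TFScore records from the three ranking components.

    Mean co-expression for a TF is the mean Pearson r with its clique
    partners — the TFs it shares at least one maximal clique with.  A TF
    with no partners (only singleton cliques) scores NaN and sorts below
    any co-operative TF.
    """
    fractions = clique_scores(cliques, tfs)
    partners: dict[str, set[str]] = {tf: set() for tf in tfs}
    for clique in cliques:
        for tf in clique:
            if tf in partners:
                partners[tf] |= clique - {tf}
    scores: list[TFScore] = []
    for tf in tfs:
        others = [t for t in partners[tf] if t in coexpr.columns]
        mean_r = float(np.nanmean(coexpr.loc[tf, others])) if others else math.nan
        scores.append(TFScore(
            tf=tf,
            clique_fraction=fractions[tf],
            mean_coexpression=mean_r,
            se_rank=int(se_ranks.get(tf, 10**9)),
        ))
    return scores
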