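"""ROSE-style super-enhancer calling.

The procedure: remove TSS-proximal peak bases, stitch nearby peaks into
regions, score each region by input-subtracted signal area, rank the
regions, and separate super-enhancers (SEs) from typical enhancers (TEs) at
the geometric inflection point of the min–max–rescaled ranked signal curve
(the "hockey stick").  Normalized coordinates — relative rank and percent
of total signal — make hockey sticks comparable across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_core import (
    GeneModel,
    GenomicInterval,
    Peak,
    SignalTrack,
    interval_signal,
    subtract_intervals,
)

__all__ = [
    "StitchedEnhancer",
    "EnhancerTable",
    "SEGeneAssignment",
    "exclude_tss",
    "stitch",
    "score_and_rank",
    "find_inflection",
    "hockey_normalize",
    "assign_genes",
    "call_super_enhancers",
]

DEFAULT_STITCH_DISTANCE = 12_500
DEFAULT_TSS_PAD = 1_250
DEFAULT_FLANK = 50_000


@dataclass
class StitchedEnhancer:
    """One stitched region with its score and SE/TE label."""

    region: GenomicInterval
    constituents: list[Peak]
    chip_signal: float = 0.0
    input_signal: float = 0.0
    net_signal: float = 0.0
    rank: int = 0
    is_se: bool = False
    relative_rank: float = float("nan")
    pct_signal: float = float("nan")

    @property
    def name(self) -> str:
        return str(self.region)


@dataclass
class EnhancerTable:
    """Ranked stitched enhancers for one sample."""

    sample_id: str
    enhancers: list[StitchedEnhancer] = field(default_factory=list)

    @property
    def n_se(self) -> int:
        return sum(e.is_se for e in self.enhancers)

    @property
    def n_te(self) -> int:
        return len(self.enhancers) - self.n_se

    def se_regions(self) -> list[GenomicInterval]:
        return [e.region for e in self.enhancers if e.is_se]

    def te_regions(self) -> list[GenomicInterval]:
        return [e.region for e in self.enhancers if not e.is_se]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "region": str(e.region),
                "chrom": e.region.chrom,
                "start": e.region.start,
                "end": e.region.end,
                "n_constituents": len(e.constituents),
                "chip_signal": e.chip_signal,
                "input_signal": e.input_signal,
                "net_signal": e.net_signal,
                "rank": e.rank,
                "is_se": e.is_se,
                "relative_rank": e.relative_rank,
                "pct_signal": e.pct_signal,
            }
            for e in self.enhancers
        ]
        return pd.DataFrame(rows)


@dataclass
class SEGeneAssignment:
    """Genes assigned to each enhancer (flank rule + nearest fallback)."""

    genes: dict[str, list[str]]          # enhancer name -> assigned gene ids
    nearest: dict[str, str | None]       # enhancer name -> nearest-TSS gene

    def se_gene_ids(self, table: EnhancerTable) -> set[str]:
        """Ids of genes assigned to any region labelled SE."""
        out: set[str] = set()
        for e in table.enhancers:
            if e.is_se:
                out.update(self.genes.get(e.name, []))
        return out


# ---------------------------------------------------------------------------


def exclude_tss(peaks: Sequence[Peak], genes: Sequence[GeneModel],
                pad: int = DEFAULT_TSS_PAD) -> list[Peak]:
    """Subtract TSS ± ``pad`` zones from peaks.

    The exclusion zone around each TSS covers bases ``[tss - pad, tss + pad]``
    inclusive.  Peaks fully inside a zone are dropped; straddling peaks are
    truncated or split into their remaining parts.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    zones_by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        zones_by_chrom.setdefault(g.chrom, []).append(
            GenomicInterval(g.chrom, max(0, g.tss - pad), g.tss + pad + 1)
        )
    out: list[Peak] = []
    for p in peaks:
        zones = zones_by_chrom.get(p.chrom, [])
        parts = subtract_intervals(p.interval, zones)
        for k, part in enumerate(parts):
            summit = p.summit if (p.summit is not None
                                  and part.start <= p.summit < part.end) else None
            name = p.name if len(parts) == 1 else f"{p.name}|{k + 1}"
            out.append(Peak(part, score=p.score, name=name, summit=summit))
    return out


def stitch(peaks: Sequence[Peak],
           distance: int = DEFAULT_STITCH_DISTANCE) -> list[tuple[GenomicInterval, list[Peak]]]:
    """Merge peaks whose gap is ≤ ``distance`` (transitive closure).

    Returns (region, constituents) with region spanning min start to max end.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    regions: list[tuple[GenomicInterval, list[Peak]]] = []
    for chrom in sorted(by_chrom):
        ps = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        cur: list[Peak] = [ps[0]]
        cur_end = ps[0].end
        for p in ps[1:]:
            if p.start - cur_end <= distance:
                cur.append(p)
                cur_end = max(cur_end, p.end)
            else:
                regions.append((GenomicInterval(chrom, cur[0].start, cur_end), cur))
                cur = [p]
                cur_end = p.end
        regions.append((GenomicInterval(chrom, cur[0].start, cur_end), cur))
    return regions


def score_and_rank(regions: Sequence[tuple[GenomicInterval, list[Peak]]],
                   chip: SignalTrack,
                   input_track: SignalTrack | None = None) -> list[StitchedEnhancer]:
    """Score regions by input-subtracted signal area and rank descending.

    ``net_signal = max(chip_area − input_area, 0)``.  Ties are broken by the
    wider region first, then the leftmost coordinate.
    """
    enhancers: list[StitchedEnhancer] = []
    for region, constituents in regions:
        chip_area = interval_signal(chip, region)
        input_area = interval_signal(input_track, region) if input_track is not None else 0.0
        enhancers.append(
            StitchedEnhancer(
                region=region,
                constituents=list(constituents),
                chip_signal=chip_area,
                input_signal=input_area,
                net_signal=max(chip_area - input_area, 0.0),
            )
        )
    enhancers.sort(key=lambda e: (-e.net_signal, -e.region.width,
                                  e.region.chrom, e.region.start))
    for i, e in enumerate(enhancers, 1):
        e.rank = i
    return enhancers


def find_inflection(net_signals: Sequence[float]) -> int:
    """Number of SEs from the geometric inflection of the ranked curve.

    ``net_signals`` must be sorted descending (rank order).  The curve of
    signal (ascending) vs rank is min–max rescaled to the unit square; the
    cutoff is the point where a unit-slope diagonal line supports the curve
    from below — the last minimizer of ``y_scaled − x_scaled``, which on a
    convex hockey stick is exactly where the discrete slope crosses 1.
    Regions with signal strictly above the signal value at the cutoff are
    SEs.

    Degenerate inputs (fewer than 3 regions, all-equal signals, or a curve
    on/above the diagonal such as a perfectly linear ramp) yield zero SEs
    with a warning.
    """
    y = np.asarray(net_signals, dtype=float)
    if np.any(np.diff(y) > 0):
        raise ValueError("net_signals must be sorted descending")
    n = len(y)
    if n < 3:
        warnings.warn("fewer than 3 regions; no SEs called", stacklevel=2)
        return 0
    asc = y[::-1]
    ymin, ymax = asc[0], asc[-1]
    if ymax == ymin:
        warnings.warn("all net signals equal; no SEs called", stacklevel=2)
        return 0
    ys = (asc - ymin) / (ymax - ymin)
    xs = np.arange(n) / (n - 1)
    gap = ys - xs
    cut = n - 1 - int(np.argmin(gap[::-1]))  # last minimizer = tangent point
    n_se = int(np.sum(y > asc[cut]))
    if n_se == 0:
        warnings.warn("ranked curve yields no region above the tangent "
                      "cutoff; no SEs called", stacklevel=2)
    return n_se


def hockey_normalize(table: EnhancerTable) -> EnhancerTable:
    """Populate relative rank and percent-of-total signal (in place).

    relative_rank_i = rank_i / (n_se + n_te);
    pct_signal_i = 100 × net_i / Σ net.
    """
    n = len(table.enhancers)
    total = sum(e.net_signal for e in table.enhancers)
    if n and total <= 0:
        raise ValueError("total net signal is zero; percent signal undefined")
    for e in table.enhancers:
        e.relative_rank = e.rank / n
        e.pct_signal = 100.0 * e.net_signal / total
    return table


def assign_genes(table: EnhancerTable, genes: Sequence[GeneModel],
                 flank: int = DEFAULT_FLANK) -> SEGeneAssignment:
    """Assign genes whose TSS lies within region ± ``flank``; nearest fallback.

    Enhancers with no gene in range get their single nearest-TSS gene.
    """
    if not genes:
        warnings.warn("empty gene set; empty assignment", stacklevel=2)
        return SEGeneAssignment(genes={e.name: [] for e in table.enhancers},
                                nearest={e.name: None for e in table.enhancers})
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    assignment: dict[str, list[str]] = {}
    nearest: dict[str, str | None] = {}
    for e in table.enhancers:
        region = e.region
        best_gene, best_dist = None, None
        in_range: list[tuple[int, str]] = []
        for g in by_chrom.get(region.chrom, []):
            dist = max(region.start - g.tss, g.tss - (region.end - 1), 0)
            if dist <= flank:
                in_range.append((g.tss, g.gene_id))
            if best_dist is None or dist < best_dist:
                best_gene, best_dist = g.gene_id, dist
        assignment[e.name] = [gid for _, gid in sorted(in_range)] or (
            [best_gene] if best_gene is not None else []
        )
        nearest[e.name] = best_gene
    return SEGeneAssignment(genes=assignment, nearest=nearest)


def call_super_enhancers(peaks: Sequence[Peak],
                         chip: SignalTrack,
                         input_track: SignalTrack | None,
                         genes: Sequence[GeneModel],
                         sample_id: str = "sample",
                         stitch_distance: int = DEFAULT_STITCH_DISTANCE,
                         tss_pad: int = DEFAULT_TSS_PAD,
                         flank: int = DEFAULT_FLANK) -> tuple[EnhancerTable, SEGeneAssignment]:
    """Full SE call: exclude TSS → stitch → score/rank → inflection → assign."""
    kept = exclude_tss(peaks, genes, pad=tss_pad)
    regions = stitch(kept, distance=stitch_distance)
    enhancers = score_and_rank(regions, chip, input_track)
    table = EnhancerTable(sample_id=sample_id, enhancers=enhancers)
    if enhancers:
        n_se = find_inflection([e.net_signal for e in enhancers])
        for e in enhancers:
            e.is_se = e.rank <= n_se
        hockey_normalize(table)
    assignment = assign_genes(table, genes, flank=flank)
    return table, assignment
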