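"""Peak occupancy classification and TF-overloaded enhancer analysis.

Peaks are assigned to mutually exclusive cis-regulatory categories with a
fixed precedence (Promoter > SE > TE > Other): a peak within the
promoter-proximal window of any gene is Promoter-bound; otherwise a peak
inside a super-enhancer or typical enhancer is Enhancer-bound; everything
else is Other.  Promoter windows are strand-aware (−1000/+200 relative to
the direction of transcription).
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Mapping, Sequence

import numpy as np

from .genomic_core import GeneModel, GenomicInterval, Peak, SignalTrack
from .se_caller import (
    EnhancerTable,
    SEGeneAssignment,
    call_super_enhancers,
)

__all__ = [
    "CATEGORIES",
    "promoter_window",
    "classify_peaks",
    "promoter_occupancy",
    "tf_overload_rank",
    "double_positive",
    "enrichment_by_region_class",
]

CATEGORIES = ("Promoter", "Enhancer_SE", "Enhancer_TE", "Other")


def promoter_window(gene: GeneModel, upstream: int = 1000,
                    downstream: int = 200) -> GenomicInterval:
    """Promoter-proximal window, strand-aware.

    + strand: [tss − upstream, tss + downstream); − strand mirrored to
    [tss − downstream, tss + upstream).
    """
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    return GenomicInterval(gene.chrom, max(start, 0), end)


def _any_overlap(iv: GenomicInterval, others: Sequence[GenomicInterval]) -> bool:
    return any(iv.overlaps(o) for o in others)


def classify_peaks(peaks: Sequence[Peak], genes: Sequence[GeneModel],
                   table: EnhancerTable,
                   promoter_upstream: int = 1000,
                   promoter_downstream: int = 200,
                   precedence: Sequence[str] = CATEGORIES
                   ) -> tuple[list[str], dict[str, float]]:
    """Category per peak plus category fractions (summing to 1).

    A peak qualifies for a category by ≥ 1 bp overlap; ties are resolved by
    ``precedence`` (Promoter first by default).
    """
    promoters = [promoter_window(g, promoter_upstream, promoter_downstream)
                 for g in genes]
    se_regions = table.se_regions()
    te_regions = table.te_regions()
    labels: list[str] = []
    for p in peaks:
        hits = set()
        if _any_overlap(p.interval, promoters):
            hits.add("Promoter")
        if _any_overlap(p.interval, se_regions):
            hits.add("Enhancer_SE")
        if _any_overlap(p.interval, te_regions):
            hits.add("Enhancer_TE")
        label = "Other"
        for cat in precedence:
            if cat in hits:
                label = cat
                break
        labels.append(label)
    n = len(peaks)
    fractions = {cat: (labels.count(cat) / n if n else 0.0) for cat in CATEGORIES}
    return labels, fractions


def promoter_occupancy(genes: Sequence[GeneModel],
                       factor_peaks: Mapping[str, Sequence[Peak]],
                       promoter_upstream: int = 1000,
                       promoter_downstream: int = 200
                       ) -> tuple[dict[str, set[str]], Counter, float | None]:
    """Per-gene factor occupancy sets over promoter windows.

    Returns (gene → factor set, combination histogram, co-occupancy
    fraction).  The combination histogram keys are "/"-joined sorted factor
    names; the co-occupancy fraction is |genes with ≥ 2 factors| / |genes
    with ≥ 1 factor| — None (flagged) when no gene is occupied.
    """
    if not factor_peaks:
        raise ValueError("at least one factor required")
    occupancy: dict[str, set[str]] = {g.gene_id: set() for g in genes}
    for factor, peaks in factor_peaks.items():
        for g in genes:
            window = promoter_window(g, promoter_upstream, promoter_downstream)
            if any(window.overlaps(p.interval) for p in peaks):
                occupancy[g.gene_id].add(factor)
    combos = Counter(
        "/".join(sorted(fs)) for fs in occupancy.values() if fs
    )
    positive = [fs for fs in occupancy.values() if fs]
    if not positive:
        warnings.warn("no occupied promoters; co-occupancy undefined", stacklevel=2)
        return occupancy, combos, None
    co = sum(len(fs) >= 2 for fs in positive) / len(positive)
    return occupancy, combos, co


def tf_overload_rank(tf_peaks: Sequence[Peak], tf_signal: SignalTrack,
                     genes: Sequence[GeneModel],
                     input_track: SignalTrack | None = None,
                     sample_id: str = "tf",
                     **rose_params) -> tuple[EnhancerTable, SEGeneAssignment]:
    """Stitch and rank a TF's own peaks/signal; regions above the inflection
    cutoff are "TF-overloaded" enhancers.  Same code path as the H3K27ac SE
    caller."""
    return call_super_enhancers(tf_peaks, tf_signal, input_track, genes,
                                sample_id=sample_id, **rose_params)


def double_positive(se_genes_a: set[str], se_genes_b: set[str]
                    ) -> dict[str, set[str]]:
    """Venn decomposition of two SE-associated gene sets."""
    return {
        "both": set(se_genes_a) & set(se_genes_b),
        "only_a": set(se_genes_a) - set(se_genes_b),
        "only_b": set(se_genes_b) - set(se_genes_a),
    }


def enrichment_by_region_class(tf_signal: SignalTrack, table: EnhancerTable
                               ) -> dict[str, dict]:
    """Per-region signal density (area/width) split by SE vs TE class."""
    out: dict[str, dict] = {}
    for cls, regions in (("SE", table.se_regions()), ("TE", table.te_regions())):
        dens = np.array([tf_signal.mean_density(r) for r in regions])
        if len(dens) == 0:
            warnings.warn(f"empty {cls} class", stacklevel=2)
            out[cls] = {"densities": dens, "median": float("nan"), "n": 0}
        else:
            out[cls] = {"densities": dens, "median": float(np.median(dens)),
                        "n": len(dens)}
    return out
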