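"""RNA-Pol2 pausing index and strand-oriented metagene profiles.

The pausing index (travelling ratio) is the ratio of mean Pol2 signal
density in a TSS-proximal window to the mean density over the gene body.
Densities rather than raw areas are used so unequal window lengths cancel.
Windows are strand-relative: "upstream" and "downstream" follow the
direction of transcription.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_core import GeneModel, GenomicInterval, SignalTrack

__all__ = [
    "PausingWindows",
    "MetageneProfile",
    "gene_window",
    "pausing_index",
    "pausing_indices",
    "metagene",
    "stratify_pausing",
]


@dataclass(frozen=True)
class PausingWindows:
    """TSS window [−upstream, +downstream) and body window [offset, TES]."""

    tss_upstream: int = 50
    tss_downstream: int = 300
    body_start_offset: int = 300

    def __post_init__(self) -> None:
        if min(self.tss_upstream, self.tss_downstream, self.body_start_offset) < 0:
            raise ValueError("window sizes must be >= 0")
        if self.tss_upstream + self.tss_downstream == 0:
            raise ValueError("TSS window is empty")


@dataclass
class MetageneProfile:
    """Per-bin mean density around anchors, oriented with transcription."""

    halfwidth: int
    binsize: int
    values: np.ndarray          # length 2 * halfwidth / binsize
    n_anchors: int

    @property
    def positions(self) -> np.ndarray:
        """Bin-start offsets relative to the anchor center."""
        return np.arange(-self.halfwidth, self.halfwidth, self.binsize)


def gene_window(gene: GeneModel, rel_start: int, rel_end: int) -> GenomicInterval | None:
    """Genomic interval for strand-relative offsets [rel_start, rel_end).

    Offset 0 is the TSS base; positive offsets run in the direction of
    transcription.  Returns None when the window is empty after clipping at
    the chromosome origin.
    """
    if rel_end <= rel_start:
        return None
    if gene.strand == "+":
        start, end = gene.tss + rel_start, gene.tss + rel_end
    else:
        start, end = gene.tss - rel_end + 1, gene.tss - rel_start + 1
    start = max(start, 0)
    if start >= end:
        return None
    return GenomicInterval(gene.chrom, start, end)


def pausing_index(track: SignalTrack, gene: GeneModel,
                  windows: PausingWindows | None = None) -> float:
    """Pausing index of one gene, or NaN when undefined.

    Undefined when the gene is shorter than the body offset or the body
    density is zero.
    """
    windows = windows or PausingWindows()
    if gene.length <= windows.body_start_offset:
        return math.nan
    tss_iv = gene_window(gene, -windows.tss_upstream, windows.tss_downstream)
    body_iv = gene_window(gene, windows.body_start_offset, gene.length)
    if tss_iv is None or body_iv is None:
        return math.nan
    body_density = track.mean_density(body_iv)
    if body_density == 0:
        return math.nan
    return track.mean_density(tss_iv) / body_density


def pausing_indices(track: SignalTrack, genes: Sequence[GeneModel],
                    windows: PausingWindows | None = None) -> pd.Series:
    """Per-gene pausing indices (NaN where undefined)."""
    return pd.Series(
        {g.gene_id: pausing_index(track, g, windows) for g in genes},
        name="pausing_index",
    )


def metagene(track: SignalTrack,
             anchors: Sequence[GenomicInterval | tuple[str, int]],
             strands: Sequence[str] | None = None,
             halfwidth: int = 2_500,
             binsize: int = 25) -> MetageneProfile:
    """Mean per-bin signal density around anchor centers.

    Anchors are intervals (center = midpoint) or (chrom, position) points.
    Bins run left to right in genomic coordinates and are reversed for −
    strand anchors so the profile is oriented with transcription.
    """
    if len(anchors) == 0:
        raise ValueError("no anchors given")
    if (2 * halfwidth) % binsize != 0:
        raise ValueError("binsize must divide 2 * halfwidth")
    nbins = 2 * halfwidth // binsize
    if strands is not None and len(strands) != len(anchors):
        raise ValueError("strands length must match anchors")
    acc = np.zeros(nbins)
    for i, anchor in enumerate(anchors):
        if isinstance(anchor, GenomicInterval):
            chrom = anchor.chrom
            center = (anchor.start + anchor.end) // 2
        else:
            chrom, center = anchor
        vals = np.empty(nbins)
        for b in range(nbins):
            s = center - halfwidth + b * binsize
            e = s + binsize
            if e <= 0:
                vals[b] = 0.0
                continue
            iv = GenomicInterval(chrom, max(s, 0), e)
            vals[b] = track.area(iv) / binsize
        if strands is not None and strands[i] == "-":
            vals = vals[::-1]
        acc += vals
    return MetageneProfile(halfwidth=halfwidth, binsize=binsize,
                           values=acc / len(anchors), n_anchors=len(anchors))


def stratify_pausing(pi_values: Mapping[str, float],
                     groups: Mapping[str, Sequence[str]],
                     compare: tuple[str, str] | None = None,
                     alternative: str = "two-sided"):
    """Group-wise pausing-index distributions plus a rank-based comparison.

    Returns ``(per_group, comparison)`` where ``per_group`` maps group name
    to an array of defined PI values and ``comparison`` is a
    :class:`~secircuit.response_analysis.GroupComparison` between the two
    ``compare`` groups (Mann–Whitney), or None when not requested or when a
    compared group has fewer than 2 defined values (flagged by warning).
    """
    from .response_analysis import rank_test

    per_group: dict[str, np.ndarray] = {}
    for name, gene_ids in groups.items():
        vals = np.array([pi_values[g] for g in gene_ids if g in pi_values],
                        dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2:
            warnings.warn(f"group {name!r} has < 2 defined pausing indices",
                          stacklevel=2)
        per_group[name] = vals
    comparison = None
    if compare is not None:
        a, b = per_group[compare[0]], per_group[compare[1]]
        if len(a) >= 2 and len(b) >= 2:
            comparison = rank_test(a, b, paired=False, alternative=alternative)
    return per_group, comparison
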