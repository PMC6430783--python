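"""Expression-side statistics for occupancy-stratified responses.

Expression lives in genes × samples FPKM matrices (pandas DataFrames with
a per-sample condition map).  The module filters active genes, computes
pseudocounted log2 fold changes between conditions, partitions genes by
regulatory annotation, and compares groups with exact or
normal-approximated rank tests (Wilcoxon signed-rank for paired data,
Mann–Whitney rank-sum for independent groups).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_core import GenomicInterval, SignalTrack, merge_intervals
from .se_caller import EnhancerTable

__all__ = [
    "GroupComparison",
    "filter_active",
    "log2fc",
    "group_by_annotation",
    "rank_test",
    "se_signal_matrix",
    "basal_expression_by_se_class",
]

EXACT_MAX_N = 25


@dataclass
class GroupComparison:
    """Outcome of a two-group rank-based comparison."""

    test: str
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    alternative: str = "two-sided"


def filter_active(expr: pd.DataFrame, threshold: float = 0.5) -> pd.Index:
    """Genes whose mean FPKM across all samples is strictly > ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    means = expr.mean(axis=1)
    return expr.index[means > threshold]


def log2fc(expr: pd.DataFrame, conditions: Mapping[str, str],
           condition_a: str, condition_b: str, pseudo: float = 1.0) -> pd.Series:
    """Per-gene log2((mean_b + pseudo) / (mean_a + pseudo))."""
    samples_a = [s for s in expr.columns if conditions.get(s) == condition_a]
    samples_b = [s for s in expr.columns if conditions.get(s) == condition_b]
    if not samples_a:
        raise ValueError(f"no samples labelled {condition_a!r}")
    if not samples_b:
        raise ValueError(f"no samples labelled {condition_b!r}")
    mean_a = expr[samples_a].mean(axis=1)
    mean_b = expr[samples_b].mean(axis=1)
    out = np.log2((mean_b + pseudo) / (mean_a + pseudo))
    out.name = f"log2fc_{condition_b}_vs_{condition_a}"
    return out


def group_by_annotation(universe: Iterable[str],
                        groups: Mapping[str, Iterable[str]],
                        none_label: str = "none") -> dict[str, list[str]]:
    """Partition ``universe`` by annotation groups, with an explicit "none".

    A gene claimed by several groups is resolved by the order of ``groups``
    (first wins); the overlap is logged as a warning.
    """
    universe = list(universe)
    assigned: dict[str, str] = {}
    overlaps = 0
    for label, members in groups.items():
        for g in members:
            if g in assigned:
                overlaps += 1
            else:
                assigned[g] = label
    if overlaps:
        warnings.warn(
            f"{overlaps} genes matched multiple groups; resolved by group order",
            stacklevel=2,
        )
    out: dict[str, list[str]] = {label: [] for label in groups}
    out[none_label] = []
    for g in universe:
        out[assigned.get(g, none_label)].append(g)
    return out


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def rank_test(a: Sequence[float], b: Sequence[float], paired: bool = False,
              alternative: str = "two-sided") -> GroupComparison:
    """Wilcoxon signed-rank (paired) or Mann–Whitney rank-sum (unpaired).

    Exact null distribution for n ≤ 25 without ties/zeros, otherwise the
    normal approximation with continuity correction.  Paired comparisons
    with all-zero differences return p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal sample sizes")
        diffs = a - b
        nonzero = diffs[diffs != 0]
        if len(nonzero) == 0:
            warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
            return GroupComparison("wilcoxon-signed-rank", 0.0, 1.0,
                                   len(a), len(b), alternative)
        method = ("exact" if len(nonzero) <= EXACT_MAX_N
                  and not _has_ties(np.abs(nonzero)) else "approx")
        res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True,
                             alternative=alternative, method=method)
        return GroupComparison("wilcoxon-signed-rank", float(res.statistic),
                               float(res.pvalue), len(a), len(b), alternative)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("unpaired test requires >= 2 values per group")
    pooled = np.concatenate([a, b])
    method = ("exact" if max(len(a), len(b)) <= EXACT_MAX_N
              and not _has_ties(pooled) else "asymptotic")
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method,
                             use_continuity=True)
    return GroupComparison("mann-whitney", float(res.statistic),
                           float(res.pvalue), len(a), len(b), alternative)


def se_signal_matrix(tables: Mapping[str, EnhancerTable],
                     tracks: Mapping[str, SignalTrack],
                     pseudo: float = 1.0) -> pd.DataFrame:
    """log2(area + pseudo) of each sample's signal over union SE regions.

    SE regions from all samples are merged (overlapping/touching regions
    collapse); rows are union regions, columns samples.  Intended as input
    for external PCA/clustering.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 samples")
    all_se: list[GenomicInterval] = []
    for table in tables.values():
        all_se.extend(table.se_regions())
    if not all_se:
        raise ValueError("no SE regions across samples; empty union")
    union = merge_intervals(all_se, gap=0)
    data = {
        sample: [np.log2(tracks[sample].area(r) + pseudo) for r in union]
        for sample in tables
    }
    return pd.DataFrame(data, index=[str(r) for r in union])


def basal_expression_by_se_class(expr: pd.DataFrame,
                                 groups: Mapping[str, Sequence[str]],
                                 compare: tuple[str, str],
                                 samples: Sequence[str] | None = None,
                                 alternative: str = "two-sided"
                                 ) -> dict:
    """Per-class FPKM distributions, medians, and a rank test between the
    designated pair of classes.

    Per-gene values are mean FPKM over ``samples`` (all columns when None).
    """
    cols = list(samples) if samples is not None else list(expr.columns)
    per_gene = expr[cols].mean(axis=1)
    dists = {
        label: per_gene.reindex([g for g in members if g in per_gene.index]).dropna().to_numpy()
        for label, members in groups.items()
    }
    medians = {label: (float(np.median(v)) if len(v) else float("nan"))
               for label, v in dists.items()}
    comparison = rank_test(dists[compare[0]], dists[compare[1]],
                           paired=False, alternative=alternative)
    return {"distributions": dists, "medians": medians, "comparison": comparison}
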