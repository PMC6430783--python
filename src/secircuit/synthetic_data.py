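"""Synthetic regulatory genomes with planted ground truth.

The generator lays out a toy chromosome as a row of fixed-width units, one
gene per unit.  A subset of units additionally hosts a planted enhancer:
super-enhancers (SEs) are clusters of 2–4 constituent peaks within
stitching range of each other, typical enhancers (TEs) are singletons.
Units are wide enough that enhancers in neighbouring units can never
stitch together, and every enhancer keeps clear of TSS exclusion zones.

On top of this layout the module emits:

* an H3K27ac-like signal track (truncated-Gaussian background noise plus
  amplitude over planted enhancer bases) with a matched pure-noise input
  track and the constituent peak calls;
* TF peaks co-localized with SE constituents at a controllable fraction;
* an RNA-Pol2 track whose TSS-window / gene-body density ratio equals a
  chosen true pausing index;
* a DNA sequence with TF motif consensi planted inside SE constituents so
  that a chosen core-regulatory-circuitry (CRC) clique is recoverable;
* an FPKM expression matrix in which SE-associated genes are overexpressed,
  CRC TF genes share a latent factor (mutual correlation), and a treatment
  condition down-regulates SE-associated genes.

Everything is a pure function of (config, seed): identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic_core import GeneModel, GenomicInterval, Peak, SignalTrack
from .pol2_metrics import PausingWindows, gene_window

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genome",
    "simulate_h3k27ac",
    "simulate_tf_peaks",
    "signal_from_peaks",
    "simulate_pol2",
    "random_pwms",
    "plant_motifs",
    "simulate_expression",
    "simulate_all",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# unit layout constants (bases)
_EDGE = 2_000          # padding from unit start to the enhancer zone
_ENH_ZONE = 10_000     # width of the per-unit enhancer zone
_TSS_GAP = 1_500       # gap between enhancer zone end and the gene TSS
_MIN_GENE = 3_000
_MAX_GENE = 12_000


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome.

    Defaults plant 8 SEs and 80 TEs with a 4:1 amplitude ratio and noise at
    one tenth of the SE amplitude, on a 6.4 Mb single-chromosome genome with
    100 genes.  The 64 kb per-gene unit keeps each planted enhancer outside
    the 50 kb gene-association flank of every neighbouring unit's gene, so
    the planted SE→gene map matches the analysis-side assignment rule.
    """

    genome_length: int = 6_400_000
    chrom: str = "chrS"
    n_genes: int = 100
    n_se: int = 8
    n_te: int = 80
    se_width: int = 800            # SE constituent width
    te_width: int = 800
    se_constituents: tuple[int, int] = (2, 4)
    se_gap: tuple[int, int] = (1_000, 2_000)   # gap between SE constituents
    se_amplitude: float = 20.0
    te_amplitude: float = 5.0
    noise_sd: float = 2.0
    noise_bin: int = 100
    tf_coloc_fraction: float = 0.9
    n_tf_background: int = 40
    tf_peak_width: int = 400
    tf_amplitude: float = 15.0
    tf_bg_amplitude: float = 5.0
    pausing_index_true: float = 3.0
    pol2_body_density: float = 2.0
    pol2_noise_sd: float = 0.2
    motif_plant_rate: float = 1.0
    n_crc_tfs: int = 3
    n_decoy_tfs: int = 5
    motif_length: int = 10
    expr_baseline_log2: float = 3.0
    expr_baseline_sd: float = 1.0
    expr_se_log2fc: float = 2.0
    treatment_log2fc: float = -1.0
    expr_noise_sd: float = 0.5
    crc_latent_sd: float = 1.0
    n_samples: int = 4             # per condition
    flank: int = 50_000            # SE-gene association distance
    stitch_distance: int = 12_500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("genome_length", "n_genes", "n_se", "n_te", "se_width",
                     "te_width", "n_tf_background", "n_samples"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tf_coloc_fraction", "motif_plant_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.pausing_index_true <= 0:
            raise ValueError("pausing_index_true must be > 0")
        if self.noise_sd < 0 or self.pol2_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    @property
    def unit(self) -> int:
        return self.genome_length // self.n_genes if self.n_genes else self.genome_length

    def rng(self, stage: str) -> np.random.Generator:
        """Per-stage generator fanned out from the global seed."""
        import zlib

        return np.random.default_rng((self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31))


@dataclass
class SimTruth:
    """Planted ground truth accumulated across the simulator stages."""

    se_regions: list[GenomicInterval] = field(default_factory=list)
    se_constituents: list[list[Peak]] = field(default_factory=list)
    te_regions: list[GenomicInterval] = field(default_factory=list)
    se_gene_ids: list[str] = field(default_factory=list)       # flank rule
    se_host_genes: list[str] = field(default_factory=list)     # one per SE
    tf_peaks: list[Peak] = field(default_factory=list)
    tf_coloc_labels: list[bool] = field(default_factory=list)
    pausing_index: dict[str, float] = field(default_factory=dict)
    crc_tfs: list[str] = field(default_factory=list)
    decoy_tfs: list[str] = field(default_factory=list)
    planted_edges: list[tuple[str, str]] = field(default_factory=list)
    motif_placements: list[dict] = field(default_factory=list)
    expression_effects: dict[str, float] = field(default_factory=dict)

    def all_enhancer_intervals(self) -> list[GenomicInterval]:
        out = [p.interval for cs in self.se_constituents for p in cs]
        out.extend(self.te_regions)
        return out

    def to_json(self, path: str | Path) -> None:
        def _iv(iv: GenomicInterval):
            return [iv.chrom, iv.start, iv.end]

        payload = {
            "se_regions": [_iv(r) for r in self.se_regions],
            "se_constituents": [[_iv(p.interval) for p in cs] for cs in self.se_constituents],
            "te_regions": [_iv(r) for r in self.te_regions],
            "se_gene_ids": self.se_gene_ids,
            "se_host_genes": self.se_host_genes,
            "tf_peaks": [_iv(p.interval) for p in self.tf_peaks],
            "tf_coloc_labels": self.tf_coloc_labels,
            "pausing_index": self.pausing_index,
            "crc_tfs": self.crc_tfs,
            "decoy_tfs": self.decoy_tfs,
            "planted_edges": [list(e) for e in self.planted_edges],
            "motif_placements": self.motif_placements,
            "expression_effects": self.expression_effects,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------


def _check_packing(config: SimConfig) -> None:
    if config.n_genes == 0:
        return
    u = config.unit
    lo, hi = config.se_constituents
    if not 1 <= lo <= hi:
        raise ValueError("se_constituents bounds must satisfy 1 <= lo <= hi")
    max_span = hi * config.se_width + (hi - 1) * config.se_gap[1]
    needed = _EDGE + _ENH_ZONE + _TSS_GAP + _MIN_GENE
    if u < needed:
        raise ValueError(
            f"genome too small: unit {u} bp < {needed} bp required per gene"
        )
    if u - _ENH_ZONE <= config.stitch_distance:
        raise ValueError(
            "unit width leaves adjacent enhancers within stitching distance"
        )
    if max_span > _ENH_ZONE or config.te_width > _ENH_ZONE:
        raise ValueError("planted enhancer span exceeds the per-unit enhancer zone")
    if config.n_se + config.n_te > config.n_genes:
        raise ValueError("need n_se + n_te <= n_genes (one enhancer per unit)")


def simulate_genome(config: SimConfig) -> tuple[list[GeneModel], str]:
    """Non-overlapping genes on alternating strands plus uniform ACGT sequence."""
    _check_packing(config)
    rng = config.rng("genome")
    codes = rng.integers(0, 4, size=config.genome_length)
    sequence = _BASES[codes].tobytes().decode("ascii")

    genes: list[GeneModel] = []
    u = config.unit
    for i in range(config.n_genes):
        u0 = i * u
        gstart = u0 + _EDGE + _ENH_ZONE + _TSS_GAP
        max_len = min(_MAX_GENE, u - (_EDGE + _ENH_ZONE + _TSS_GAP))
        glen = int(rng.integers(_MIN_GENE, max_len + 1))
        gend = gstart + glen
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            tss, tes = gstart, gend - 1
        else:
            tss, tes = gend - 1, gstart
        genes.append(GeneModel(f"gene{i:04d}", config.chrom, strand, tss, tes,
                               name=f"gene{i:04d}"))
    return genes, sequence


def _noise_pieces(config: SimConfig, rng: np.random.Generator) -> list[tuple[str, int, int, float]]:
    """Truncated-Gaussian background noise in fixed-width bins."""
    if config.noise_sd == 0:
        return []
    nbins = int(np.ceil(config.genome_length / config.noise_bin))
    vals = np.maximum(rng.normal(0.0, config.noise_sd, size=nbins), 0.0)
    edges = np.minimum(np.arange(nbins + 1) * config.noise_bin, config.genome_length)
    return [
        (config.chrom, int(edges[i]), int(edges[i + 1]), float(vals[i]))
        for i in range(nbins) if vals[i] > 0 and edges[i] < edges[i + 1]
    ]


def simulate_h3k27ac(genes: Sequence[GeneModel], config: SimConfig,
                     truth: SimTruth | None = None
                     ) -> tuple[SignalTrack, SignalTrack, list[Peak], SimTruth]:
    """H3K27ac-like chip track, matched input track, constituent peaks, truth."""
    _check_packing(config)
    truth = truth or SimTruth()
    rng = config.rng("h3k27ac")
    u = config.unit
    units = rng.permutation(config.n_genes)
    se_units = sorted(units[: config.n_se].tolist())
    te_units = sorted(units[config.n_se: config.n_se + config.n_te].tolist())

    pieces: list[tuple[str, int, int, float]] = []
    peaks: list[Peak] = []

    for k, ui in enumerate(se_units):
        zone0 = ui * u + _EDGE
        ncons = int(rng.integers(config.se_constituents[0], config.se_constituents[1] + 1))
        gaps = rng.integers(config.se_gap[0], config.se_gap[1] + 1, size=max(ncons - 1, 0))
        span = ncons * config.se_width + int(np.sum(gaps))
        slack = _ENH_ZONE - span
        start = zone0 + int(rng.integers(0, slack + 1))
        constituents: list[Peak] = []
        pos = start
        for c in range(ncons):
            iv = GenomicInterval(config.chrom, pos, pos + config.se_width)
            constituents.append(Peak(iv, score=config.se_amplitude, name=f"se{k}_c{c}"))
            pieces.append((config.chrom, iv.start, iv.end, config.se_amplitude))
            if c < ncons - 1:
                pos = iv.end + int(gaps[c])
        peaks.extend(constituents)
        truth.se_constituents.append(constituents)
        truth.se_regions.append(
            GenomicInterval(config.chrom, constituents[0].start, constituents[-1].end)
        )
        truth.se_host_genes.append(f"gene{ui:04d}")

    for k, ui in enumerate(te_units):
        zone0 = ui * u + _EDGE
        start = zone0 + int(rng.integers(0, _ENH_ZONE - config.te_width + 1))
        iv = GenomicInterval(config.chrom, start, start + config.te_width)
        peaks.append(Peak(iv, score=config.te_amplitude, name=f"te{k}"))
        pieces.append((config.chrom, iv.start, iv.end, config.te_amplitude))
        truth.te_regions.append(iv)

    chip = SignalTrack.from_pieces(pieces + _noise_pieces(config, rng))
    input_track = SignalTrack.from_pieces(_noise_pieces(config, config.rng("input")))

    # SE-associated genes under the flank rule used downstream
    se_gene_ids: set[str] = set()
    for region in truth.se_regions:
        for g in genes:
            if g.chrom != region.chrom:
                continue
            dist = max(region.start - g.tss, g.tss - (region.end - 1), 0)
            if dist <= config.flank:
                se_gene_ids.add(g.gene_id)
    truth.se_gene_ids = sorted(se_gene_ids)
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return chip, input_track, peaks, truth


def simulate_tf_peaks(truth: SimTruth, config: SimConfig) -> list[Peak]:
    """TF peaks on SE constituents (probability ``tf_coloc_fraction``) plus
    weak solitary background peaks outside all planted enhancers.

    Background peaks model scattered low-occupancy binding: they carry
    ``tf_bg_amplitude`` and are kept more than a stitching distance apart so
    they remain singleton regions under stitching.
    """
    rng = config.rng("tf_peaks")
    peaks: list[Peak] = []
    labels: list[bool] = []
    for cs in truth.se_constituents:
        for p in cs:
            if rng.random() < config.tf_coloc_fraction:
                peaks.append(Peak(p.interval, score=config.tf_amplitude,
                                  name=f"tf_{p.name}"))
                labels.append(True)

    enh = sorted(truth.all_enhancer_intervals(), key=lambda iv: iv.start)
    enh_starts = np.array([iv.start for iv in enh], dtype=np.int64)
    enh_ends = np.array([iv.end for iv in enh], dtype=np.int64)
    w = config.tf_peak_width
    bg_starts: list[int] = []
    attempts = 0
    while len(bg_starts) < config.n_tf_background and \
            attempts < 200 * max(config.n_tf_background, 1):
        attempts += 1
        start = int(rng.integers(0, config.genome_length - w))
        i = np.searchsorted(enh_starts, start + w)
        clash = i > 0 and enh_ends[i - 1] > start
        if i < len(enh_starts):
            clash = clash or enh_starts[i] < start + w
        if clash:
            continue
        if any(abs(start - s) <= config.stitch_distance + w for s in bg_starts):
            continue
        bg_starts.append(start)
    for k, start in enumerate(sorted(bg_starts)):
        peaks.append(Peak(GenomicInterval(config.chrom, start, start + w),
                          score=config.tf_bg_amplitude, name=f"tf_bg{k}"))
        labels.append(False)
    truth.tf_peaks = peaks
    truth.tf_coloc_labels = labels
    return peaks


def signal_from_peaks(peaks: Sequence[Peak], config: SimConfig,
                      amplitude: float | None = None,
                      stage: str = "tf_signal") -> SignalTrack:
    """Per-peak-score signal density plus the standard background noise.

    ``amplitude`` overrides every peak's score when given.
    """
    rng = config.rng(stage)
    pieces = [(p.chrom, p.start, p.end,
               p.score if amplitude is None else amplitude) for p in peaks]
    return SignalTrack.from_pieces(pieces + _noise_pieces(config, rng))


def simulate_pol2(genes: Sequence[GeneModel], config: SimConfig,
                  windows: PausingWindows | None = None,
                  truth: SimTruth | None = None) -> tuple[SignalTrack, SimTruth]:
    """Pol2 track with TSS-window density = pausing_index_true × body density.

    Densities are placed on exactly the strand-relative windows the pausing
    estimator reads, so with zero noise the estimator inverts the
    construction exactly.
    """
    windows = windows or PausingWindows()
    truth = truth or SimTruth()
    rng = config.rng("pol2")
    d_body = config.pol2_body_density
    d_tss = config.pausing_index_true * d_body
    pieces: list[tuple[str, int, int, float]] = []
    for g in genes:
        tss_iv = gene_window(g, -windows.tss_upstream, windows.tss_downstream)
        body_iv = gene_window(g, windows.body_start_offset, g.length)
        if body_iv is None:
            continue
        pieces.append((g.chrom, tss_iv.start, tss_iv.end, d_tss))
        pieces.append((g.chrom, body_iv.start, body_iv.end, d_body))
        truth.pausing_index[g.gene_id] = config.pausing_index_true
    if config.pol2_noise_sd > 0:
        noise_cfg = dataclasses.replace(config, noise_sd=config.pol2_noise_sd)
        pieces += _noise_pieces(noise_cfg, rng)
    return SignalTrack.from_pieces(pieces), truth


# ---------------------------------------------------------------------------
# Motifs and CRC planting
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def random_pwms(names: Sequence[str], length: int,
                rng: np.random.Generator) -> dict[str, "object"]:
    """Near-one-hot PWMs with distinct random consensus sequences."""
    from .crc import PWM

    pwms: dict[str, PWM] = {}
    used: set[str] = set()
    for name in names:
        for _ in range(1000):
            codes = rng.integers(0, 4, size=length)
            cons = _BASES[codes].tobytes().decode("ascii")
            if cons not in used and _revcomp(cons) not in used:
                used.add(cons)
                break
        else:  # pragma: no cover
            raise RuntimeError("could not draw distinct consensus sequences")
        matrix = np.full((length, 4), 0.01)
        matrix[np.arange(length), codes] = 0.97
        pwms[name] = PWM(name=name, matrix=matrix)
    return pwms


def plant_motifs(sequence: str, pwms: dict, truth: SimTruth,
                 config: SimConfig) -> tuple[str, SimTruth]:
    """Write motif consensi into SE constituent sequence per planted edge.

    TF identities are the host genes of the first ``n_crc_tfs +
    n_decoy_tfs`` planted SEs.  Planted edges: every ordered pair (including
    self) among the CRC TFs, plus a self-edge for each decoy TF (decoys are
    auto-regulated but not mutually connected).  Each edge i→j is realised
    with probability ``motif_plant_rate`` by writing TF i's consensus
    (forward or reverse-complement) into a constituent of TF j's SE.
    """
    rng = config.rng("motifs")
    n_tfs = config.n_crc_tfs + config.n_decoy_tfs
    if n_tfs > len(truth.se_host_genes):
        raise ValueError(
            f"need at least {n_tfs} planted SEs to host TF genes, "
            f"have {len(truth.se_host_genes)}"
        )
    tf_genes = truth.se_host_genes[:n_tfs]
    truth.crc_tfs = tf_genes[: config.n_crc_tfs]
    truth.decoy_tfs = tf_genes[config.n_crc_tfs:]

    edges: list[tuple[str, str]] = []
    for a in truth.crc_tfs:
        for b in truth.crc_tfs:
            edges.append((a, b))
    for d in truth.decoy_tfs:
        edges.append((d, d))

    seq = bytearray(sequence, "ascii")
    occupied: list[tuple[int, int]] = []
    se_of = {g: i for i, g in enumerate(truth.se_host_genes)}
    for src, dst in edges:
        if rng.random() >= config.motif_plant_rate:
            continue
        cons = pwms[src].consensus
        m = len(cons)
        constituents = truth.se_constituents[se_of[dst]]
        placed = False
        for _ in range(50):
            c = constituents[int(rng.integers(0, len(constituents)))]
            pos = int(rng.integers(c.start, c.end - m + 1))
            if any(pos < e and pos + m > s for s, e in occupied):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            word = cons if strand == "+" else _revcomp(cons)
            seq[pos: pos + m] = word.encode("ascii")
            occupied.append((pos, pos + m))
            truth.motif_placements.append(
                {"tf": src, "target_tf": dst, "position": pos, "strand": strand}
            )
            truth.planted_edges.append((src, dst))
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place motif for edge {src}->{dst}")
    return seq.decode("ascii"), truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(genes: Sequence[GeneModel], truth: SimTruth,
                        config: SimConfig
                        ) -> tuple[pd.DataFrame, dict[str, str], SimTruth]:
    """FPKM matrix (genes × samples) for control and treatment conditions.

    log2 expression = baseline + SE effect + latent CRC factor + noise;
    treatment shifts SE-associated genes by ``treatment_log2fc``.
    """
    if config.n_samples < 2:
        raise ValueError("need >= 2 samples per condition")
    rng = config.rng("expression")
    gene_ids = [g.gene_id for g in genes]
    se_set = set(truth.se_gene_ids)
    crc_set = set(truth.crc_tfs)
    samples = [f"ctrl_{i + 1}" for i in range(config.n_samples)] + \
              [f"trt_{i + 1}" for i in range(config.n_samples)]
    conditions = {s: ("control" if s.startswith("ctrl") else "treatment")
                  for s in samples}

    baseline = rng.normal(config.expr_baseline_log2, config.expr_baseline_sd,
                          size=len(gene_ids))
    latent = rng.normal(0.0, 1.0, size=len(samples))
    noise = rng.normal(0.0, config.expr_noise_sd, size=(len(gene_ids), len(samples)))

    log2x = np.empty((len(gene_ids), len(samples)))
    for i, gid in enumerate(gene_ids):
        mu = baseline[i]
        if gid in se_set:
            mu = mu + config.expr_se_log2fc
        row = np.full(len(samples), mu)
        if gid in se_set:
            trt = np.array([conditions[s] == "treatment" for s in samples])
            row = row + config.treatment_log2fc * trt
        if gid in crc_set:
            row = row + config.crc_latent_sd * latent
        log2x[i] = row + noise[i]
        truth.expression_effects[gid] = (
            config.expr_se_log2fc if gid in se_set else 0.0
        )
    fpkm = np.power(2.0, log2x)
    expr = pd.DataFrame(fpkm, index=pd.Index(gene_ids, name="gene_id"),
                        columns=samples)
    return expr, conditions, truth


# ---------------------------------------------------------------------------

def simulate_all(config: SimConfig) -> dict:
    """Run every simulator stage; returns a dict of all artifacts + truth."""
    genes, sequence = simulate_genome(config)
    chip, input_track, peaks, truth = simulate_h3k27ac(genes, config)
    tf_peaks = simulate_tf_peaks(truth, config)
    tf_track = signal_from_peaks(tf_peaks, config)
    pol2_track, truth = simulate_pol2(genes, config, truth=truth)
    n_tfs = config.n_crc_tfs + config.n_decoy_tfs
    pwms = {}
    if n_tfs > 0 and n_tfs <= len(truth.se_host_genes):
        pwms = random_pwms(truth.se_host_genes[:n_tfs], config.motif_length,
                           config.rng("pwms"))
        sequence, truth = plant_motifs(sequence, pwms, truth, config)
    expr, conditions, truth = simulate_expression(genes, truth, config)
    return {
        "config": config,
        "genes": genes,
        "sequence": sequence,
        "chip": chip,
        "input": input_track,
        "peaks": peaks,
        "tf_peaks": tf_peaks,
        "tf_track": tf_track,
        "pol2": pol2_track,
        "pwms": pwms,
        "expression": expr,
        "conditions": conditions,
        "truth": truth,
    }
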