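# Methods

This note documents the models, conventions and numerical choices behind
`secircuit`, and what its synthetic benchmarks do and do not demonstrate.

## Coordinates and signal model

All coordinates are 0-based, half-open `[start, end)`; GTF input is
converted at the reader boundary. TSS and TES are single base positions,
with `tss > tes` on the − strand. A `SignalTrack` is a non-negative
piecewise-constant density per base; the signal in a region is the *area*
`Σ value × overlap_width` ("area under the peak"), so quantities are
invariant to how a constant stretch is split into bedGraph records.
Chromosomes absent from a track quantify to 0 — sparse tracks are normal,
not an error.

## Super-enhancer calling

The caller follows the classic rank-ordering recipe:

1. **TSS exclusion** — bases within ±`tss_pad` (default 1250 bp, inclusive
   on both ends) of any TSS are subtracted from peaks; fully covered peaks
   are dropped, straddling peaks are split. Exclusion runs before
   stitching, so promoter-proximal signal never contributes to ranking.
2. **Stitching** — peaks with gap ≤ `stitch_distance` (default 12,500 bp,
   the conventional value) merge transitively; the region spans min start
   to max end of its constituents.
3. **Scoring** — `net = max(chip_area − input_area, 0)` over the stitched
   span; ties are broken deterministically (wider region, then leftmost).
4. **Inflection cutoff** — ranked net signals are plotted ascending and
   min–max rescaled to the unit square. The cutoff is the *diagonal
   tangent point*: the last index minimizing `y_scaled − x_scaled`, i.e.
   where a unit-slope line supports the curve from below. On a convex
   hockey stick this coincides with the first discrete-slope crossing of
   1; unlike the first-crossing rule it is robust to a single unusually
   low region at the bottom of the curve, which would otherwise make the
   first ascending segment exceed unit slope and label nearly everything
   an SE. Regions strictly above the cutoff value are SEs. Degenerate
   inputs (< 3 regions, all-equal or linear curves) yield zero SEs with a
   warning rather than an error, so tiny runs fail soft.
5. **Gene assignment** — each region takes every gene whose TSS lies
   within ±`flank` (default 50 kb), falling back to the nearest-TSS gene;
   an "SE-associated gene" is any gene assigned to an SE region. The
   hockey-stick normalization (`relative_rank = rank / n`,
   `pct_signal = 100·net/Σnet`) holds by construction and is asserted to
   1e-6.

TF "overload" ranking reuses exactly this code path on a TF's own
peaks/signal, so its behaviour is identical by construction.

## Occupancy classes

Promoter windows are strand-aware: −1000/+200 bp relative to the direction
of transcription. Categories are mutually exclusive with precedence
Promoter > Enhancer(SE) > Enhancer(TE) > Other, qualifying by ≥ 1 bp
overlap; the precedence is configurable. Per-gene factor occupancy is a
set (duplicate peaks are idempotent); the co-occupancy fraction is
|genes with ≥ 2 factors| / |genes with ≥ 1 factor| and is flagged
undefined when no promoter is occupied. "Co-localization" of two peak sets
defaults to ≥ 1 shared base, exposed as `min_bp`.

## Pol2 metrics

The pausing index is a ratio of *densities* (area/width), TSS window
−50/+300 over body +300→TES by default — a common travelling-ratio
convention; window sizes are parameters, and quantitative pausing values
are therefore comparable only within a fixed window choice. Genes shorter
than the body offset, or with zero body density, return NaN and are
excluded from group statistics. Metagene profiles average per-bin density
(default 25 bp bins over ±2.5 kb) across anchors, with bin order reversed
for − strand anchors so profiles are oriented with transcription.

## CRC inference

PWMs store per-position base probabilities; scanning scores
`Σ log2((p + pc·bg) / ((1+pc)·bg))` with pseudocount 0.01 and uniform
background, on both strands, with N contributing 0. The default hit
threshold is 80% of each PWM's maximum score — for a sharply peaked 10-mer
PWM this tolerates no mismatch, keeping the false-positive rate per SE
scan at the 10⁻³ level. Scanning uses the full SE region sequence; valley
or constituent-restricted scanning would be a stricter variant and is not
implemented.

A TF is a node iff it is expressed (mean FPKM > 0.5), SE-associated, and
its own motif hits its own SE (auto-regulation). Edges require ≥ 1 hit;
cliques are maximal cliques of the *mutual* (bidirectional) edge graph via
Bron–Kerbosch with pivoting, capped at 25 nodes. TFs are ranked by
(clique fraction ↓, mean Pearson r with clique partners ↓, own SE rank ↑).
Partner-restricted co-expression (rather than against all candidate TFs)
is the deliberate choice: it measures exactly the "co-operating" property
the clique claims, and leaves partner-less singletons ranked below any
co-operative TF. Co-expression is computed on log2(FPKM+1) over basal
(control) samples.

## Expression statistics

Active genes are mean FPKM strictly > 0.5. The response measure is the
pseudocounted ratio `log2((mean_b + 1)/(mean_a + 1))` of condition means —
not a shrunken differential-expression estimate; the stratified-response
conclusions are rank-based across gene classes, which this measure
supports. Group comparisons use the Mann–Whitney rank-sum test for
independent gene groups and the Wilcoxon signed-rank test where a true
pairing exists (`paired=True`); gene-class comparisons are structurally
unpaired, so unpaired is the default even where a signed-rank test is the
conventional label for such figures. Exact null distributions are used up
to n = 25 without ties/zeros, otherwise the normal approximation with
continuity correction; all-zero paired differences give p = 1 with a
warning. The SE signal matrix is `log2(area + 1)` of each sample's chip
signal over the union of SE regions (overlapping regions merged), intended
for external PCA/clustering.

## Synthetic data: what it emulates

The generator lays the genome out in fixed 64 kb units, one gene per unit
on alternating strands. A unit's enhancer zone is padded so that (a)
enhancers in neighbouring units can never stitch together and (b) every
planted enhancer lies outside the 50 kb association flank of neighbouring
genes — the planted SE→gene map therefore coincides with the analysis-side
assignment rule. SEs are clusters of 2–4 constituent peaks (800 bp, gaps
1–2 kb) so stitching is actually exercised; TEs are singletons. Defaults:
8 SEs, 80 TEs, amplitudes 20 vs 5 (4:1), truncated-Gaussian background
noise with SD 2 (a tenth of the SE amplitude) in 100 bp bins, and a
matched pure-noise input track.

TF peaks land on SE constituents with probability `tf_coloc_fraction`
(default 0.9) at amplitude 15; background TF peaks are weak (amplitude 5)
and kept more than a stitching distance apart, emulating scattered
solitary binding rather than clustered occupancy. Pol2 tracks place
density `PI_true × d_body` on exactly the TSS window the estimator reads,
so the noiseless estimator inverts the construction; with noise the
truncated-noise floor biases the ratio down by ~2–3% at the default
settings, well within the 10% recovery tolerance. Motif consensi are
written into SE constituents for every ordered pair of the 3 designated
CRC TFs plus a self-edge per decoy TF, so decoys are auto-regulated
candidates but not co-operative. Expression is Gaussian on the log2 scale
(baseline N(3,1), SE effect +2, treatment effect −1 on SE genes, noise SD
0.5, 4 samples per condition), with a unit-variance latent factor shared
by CRC TF genes giving pairwise r ≈ 0.8 in expectation; FPKMs are the
exponentiated values. Effect sizes are the package's chosen study
conditions, not calibrated to any particular dataset.

Everything is a pure function of (config, seed); the pipeline fans a
single seed out to per-stage generators by hashing stage names, so adding
a stage does not perturb earlier draws.

**What passing does not show**: the generator has no read-level noise, no
fragment-length or GC structure, no peak-caller artifacts, no blacklisted
regions, one chromosome, and cleanly separated amplitude classes. Perfect
recovery here demonstrates the correctness of the algorithmic chain, not
its selectivity on real ChIP-seq, where the hockey stick is smooth and the
SE/TE boundary genuinely ambiguous.

## Problem sizes

The bundled configurations are desk-scale by design: 6.4 Mb genomes with
~100 genes for recovery experiments (20 seeds), 4.1 Mb with 13 SEs for CRC
recovery (3 planted TFs + 10 decoys, 20 seeds), and 12.8 Mb with 200 genes
for the stratified-response calibration (10 seeds). The complete test
suite runs in well under a minute; the acceptance script in ~20 s.

## Known limitations

- Stitching does not apply a blacklist and will happily join regions
  across assembly gaps; real-data use should pre-filter peaks.
- `find_inflection` returns a count, not an uncertainty; near-boundary
  regions flip SE/TE label under small signal perturbations.
- The CRC expressed-TF filter is the simple mean-FPKM threshold; no
  TF-family collapsing of similar motifs is attempted, so paralogous PWMs
  can inflate each other's edges.
- bigWig input is not supported; convert to bedGraph first.
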