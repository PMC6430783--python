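# secircuit

Super-enhancer landscapes and core transcriptional regulatory circuitry,
reimplemented as a tested, desk-scale pipeline.

## The problem

In many cancers, a small set of *super-enhancers* (SEs) — clusters of
enhancers carrying exceptionally high aggregate H3K27ac signal — drives the
expression of lineage and oncogene programs, and a handful of SE-associated,
auto-regulated transcription factors (TFs) wire themselves into a *core
regulatory circuitry* (CRC) of mutually reinforcing feed-forward loops.
Dissecting such a circuit from ChIP-seq and RNA-seq requires a chain of
genomic analyses that are usually scattered across ad-hoc scripts:

1. **SE calling** (ROSE-style): TSS-proximal peak bases (±1250 bp) are
   excluded, peaks within 12.5 kb are stitched into regions, regions are
   ranked by input-subtracted signal area, and the geometric inflection of
   the ranked "hockey stick" separates SEs from typical enhancers (TEs).
   The curve is normalized per sample by
   *relative rank* = rank / (n_SE + n_TE) and
   *percent signal* = 100 · net_i / Σ net.
2. **Occupancy classes**: peaks fall into mutually exclusive categories —
   Promoter (−1000/+200 bp of the TSS, strand-aware), Enhancer(SE),
   Enhancer(TE), Other — and genes acquire per-factor promoter occupancy
   sets (e.g. BRD2/BRD4 co-occupancy).
3. **TF overload and double-positive SEs**: the same stitch-rank-cut
   machinery applied to a TF's own peaks yields TF-overloaded enhancers;
   genes supported by both H3K27ac-SEs and TF-overloaded SEs are the
   "double-positive" set.
4. **RNA-Pol2 pausing**: the pausing index of a gene is the mean Pol2
   density in a TSS window (−50/+300) divided by the mean density over the
   gene body (+300 → TES); metagene profiles average density in 25 bp bins
   over ±2.5 kb around anchors, oriented by strand.
5. **CRC inference**: TF position-weight matrices are scanned (log-odds,
   both strands) across SE sequences; a TF is a CRC candidate iff its own
   motif hits its own SE (auto-regulation); maximal cliques of mutually
   connected TFs are enumerated (Bron–Kerbosch) and TFs are ranked by
   clique participation, co-expression with clique partners, and SE rank.
6. **Stratified response**: genes are partitioned by occupancy/SE class and
   their log2 fold changes under treatment are compared with exact
   Wilcoxon / Mann–Whitney rank tests.

`secircuit` implements this chain as a library plus a thin CLI, together
with a **synthetic-data generator** that plants every ground truth the
chain is supposed to recover (SE coordinates, TF co-localization, pausing
indices, motif placements, CRC cliques, expression effects), so the whole
pipeline is testable end-to-end.

## Worked example

```bash
secircuit run --seed 1 --out runs/demo
```

runs simulate → call-se → annotate → pol2 → crc → respond on a 6.4 Mb toy
genome (100 genes, 8 planted SEs, 80 TEs) and prints:

```json
{
 "n_se_called": 8,
 "se_precision": 1.0,
 "se_recall": 1.0,
 "mean_pausing_index": 2.92,
 "top_tfs": ["gene0004", "gene0040", "gene0037"],
 "response_p": 1.63e-07
}
```

All 8 planted SEs are recovered exactly (precision = recall = 1.0); the
mean estimated pausing index is within 3% of the planted value 3 (the
small deficit is the truncated-noise floor entering the denominator); the
three planted CRC TFs occupy the top 3 ranks; and the SE-associated gene
group responds to the simulated treatment significantly more negatively
than the background (one-sided Mann–Whitney p ≈ 2 × 10⁻⁷, median log2FC
−0.91 vs +0.02).

Each stage can also be run standalone on the previous stage's files, e.g.

```bash
secircuit call-se --peaks runs/demo/sim/h3k27ac_peaks.narrowPeak \
  --chip runs/demo/sim/h3k27ac.bedgraph --input runs/demo/sim/input.bedgraph \
  --genes runs/demo/sim/genes.gtf --out se.tsv
```

## Layout

```
src/secircuit/
  genomic_core.py    # intervals, signal tracks, BED/narrowPeak/bedGraph/GTF/FASTA
  synthetic_data.py  # planted-truth genome/signal/motif/expression simulators
  se_caller.py       # exclude -> stitch -> rank -> inflection -> assign genes
  occupancy.py       # peak categories, promoter occupancy, TF overload, Venn
  pol2_metrics.py    # pausing index, metagene profiles
  crc.py             # PWM scanning, CRC graph, cliques, TF ranking
  response_analysis.py  # active filter, log2FC, rank tests, SE signal matrix
  pipeline.py, cli.py   # orchestration and the `secircuit` command
```
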