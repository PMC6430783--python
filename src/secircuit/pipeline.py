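"""End-to-end orchestration of the synthetic demonstration pipeline.

Stages run in dependency order — simulate → call-se → annotate → pol2 →
crc → respond — each reading the previous stage's files, so any stage can
also be run standalone.  The whole run is a pure function of (config,
seed): a rerun with the same config produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crc as crc_mod
from . import genomic_core as gc
from . import occupancy as occ
from . import pol2_metrics as p2
from . import response_analysis as resp
from . import se_caller as rose
from .synthetic_data import SimConfig, simulate_all

__all__ = ["PipelineConfig", "run_pipeline", "region_recovery"]


@dataclass
class PipelineConfig:
    """Flat configuration for the full pipeline; unknown keys are rejected."""

    sim: SimConfig = field(default_factory=SimConfig)
    stitch_distance: int = rose.DEFAULT_STITCH_DISTANCE
    tss_pad: int = rose.DEFAULT_TSS_PAD
    flank: int = rose.DEFAULT_FLANK
    tss_upstream: int = 50
    tss_downstream: int = 300
    body_start_offset: int = 300
    scan_threshold_frac: float = 0.8
    paired_test: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        # the global seed fans out to all simulator stages
        self.sim = dataclasses.replace(self.sim, seed=self.seed,
                                       flank=self.flank,
                                       stitch_distance=self.stitch_distance)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sim_fields = {f.name for f in fields(SimConfig)}
        own_fields = {f.name for f in fields(cls)} - {"sim"}
        sim_kwargs, own_kwargs = {}, {}
        for key, value in raw.items():
            if key in own_fields:
                own_kwargs[key] = value
            elif key in sim_fields:
                sim_kwargs[key] = value
            else:
                raise ValueError(f"unknown configuration key {key!r}")
        return cls(sim=SimConfig(**sim_kwargs), **own_kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        return cls.from_dict(raw)


# ---------------------------------------------------------------------------
# Table serialization (stage isolation)
# ---------------------------------------------------------------------------

def write_enhancer_table(table: rose.EnhancerTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index=False)


def read_enhancer_table(path: str | Path, sample_id: str = "sample") -> rose.EnhancerTable:
    df = pd.read_csv(path, sep="\t")
    enhancers = []
    for _, row in df.iterrows():
        e = rose.StitchedEnhancer(
            region=gc.GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
            constituents=[],
            chip_signal=float(row["chip_signal"]),
            input_signal=float(row["input_signal"]),
            net_signal=float(row["net_signal"]),
            rank=int(row["rank"]),
            is_se=bool(row["is_se"]),
            relative_rank=float(row["relative_rank"]),
            pct_signal=float(row["pct_signal"]),
        )
        enhancers.append(e)
    enhancers.sort(key=lambda e: e.rank)
    return rose.EnhancerTable(sample_id=sample_id, enhancers=enhancers)


def write_assignment(assignment: rose.SEGeneAssignment, path: str | Path) -> None:
    rows = [
        {"enhancer": name, "genes": ",".join(genes),
         "nearest": assignment.nearest.get(name) or ""}
        for name, genes in assignment.genes.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_assignment(path: str | Path) -> rose.SEGeneAssignment:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    genes = {row["enhancer"]: ([g for g in str(row["genes"]).split(",") if g])
             for _, row in df.iterrows()}
    nearest = {row["enhancer"]: (row["nearest"] or None) for _, row in df.iterrows()}
    return rose.SEGeneAssignment(genes=genes, nearest=nearest)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    art = simulate_all(config.sim)
    gc.write_gtf(art["genes"], outdir / "genes.gtf")
    gc.write_fasta({config.sim.chrom: art["sequence"]}, outdir / "genome.fa")
    gc.write_bed(art["peaks"], outdir / "h3k27ac_peaks.narrowPeak", narrowpeak=True)
    gc.write_bedgraph(art["chip"], outdir / "h3k27ac.bedgraph")
    gc.write_bedgraph(art["input"], outdir / "input.bedgraph")
    gc.write_bed(art["tf_peaks"], outdir / "tf_peaks.narrowPeak", narrowpeak=True)
    gc.write_bedgraph(art["tf_track"], outdir / "tf.bedgraph")
    gc.write_bedgraph(art["pol2"], outdir / "pol2.bedgraph")
    if art["pwms"]:
        crc_mod.write_jaspar(list(art["pwms"].values()), outdir / "motifs.jaspar")
    art["expression"].to_csv(outdir / "expression.tsv", sep="\t")
    pd.Series(art["conditions"], name="condition").rename_axis("sample") \
        .to_csv(outdir / "conditions.tsv", sep="\t")
    art["truth"].to_json(outdir / "truth.json")
    return art


def stage_call_se(config: PipelineConfig, simdir: Path, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    peaks = gc.read_intervals(simdir / "h3k27ac_peaks.narrowPeak", "narrowPeak")
    chip = gc.read_signal(simdir / "h3k27ac.bedgraph")
    input_track = gc.read_signal(simdir / "input.bedgraph")
    genes = gc.read_gtf(simdir / "genes.gtf")
    table, assignment = rose.call_super_enhancers(
        peaks, chip, input_track, genes, sample_id="h3k27ac",
        stitch_distance=config.stitch_distance, tss_pad=config.tss_pad,
        flank=config.flank,
    )
    write_enhancer_table(table, outdir / "se_table.tsv")
    write_assignment(assignment, outdir / "se_genes.tsv")


def stage_annotate(config: PipelineConfig, simdir: Path, sedir: Path,
                   outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    genes = gc.read_gtf(simdir / "genes.gtf")
    table = read_enhancer_table(sedir / "se_table.tsv", "h3k27ac")
    tf_peaks = gc.read_intervals(simdir / "tf_peaks.narrowPeak", "narrowPeak")
    tf_track = gc.read_signal(simdir / "tf.bedgraph")

    labels, fractions = occ.classify_peaks(tf_peaks, genes, table)
    pd.DataFrame({
        "peak": [p.name for p in tf_peaks],
        "chrom": [p.chrom for p in tf_peaks],
        "start": [p.start for p in tf_peaks],
        "end": [p.end for p in tf_peaks],
        "category": labels,
    }).to_csv(outdir / "peak_categories.tsv", sep="\t", index=False)

    enr = occ.enrichment_by_region_class(tf_track, table)
    tf_table, tf_assignment = occ.tf_overload_rank(
        tf_peaks, tf_track, genes,
        input_track=gc.read_signal(simdir / "input.bedgraph"),
        stitch_distance=config.stitch_distance, tss_pad=config.tss_pad,
        flank=config.flank,
    )
    write_enhancer_table(tf_table, outdir / "tf_table.tsv")
    write_assignment(tf_assignment, outdir / "tf_genes.tsv")

    se_assignment = read_assignment(sedir / "se_genes.tsv")
    se_table = read_enhancer_table(sedir / "se_table.tsv", "h3k27ac")
    venn = occ.double_positive(
        se_assignment.se_gene_ids(se_table), tf_assignment.se_gene_ids(tf_table)
    )
    payload = {
        "category_fractions": fractions,
        "enrichment": {cls: {"median": d["median"], "n": d["n"]}
                       for cls, d in enr.items()},
        "venn": {k: sorted(v) for k, v in venn.items()},
    }
    with open(outdir / "annotation.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def stage_pol2(config: PipelineConfig, simdir: Path, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    genes = gc.read_gtf(simdir / "genes.gtf")
    track = gc.read_signal(simdir / "pol2.bedgraph")
    windows = p2.PausingWindows(config.tss_upstream, config.tss_downstream,
                                config.body_start_offset)
    pi = p2.pausing_indices(track, genes, windows)
    pi.rename_axis("gene_id").to_csv(outdir / "pausing_index.tsv", sep="\t")
    anchors = [(g.chrom, g.tss) for g in genes]
    strands = [g.strand for g in genes]
    profile = p2.metagene(track, anchors, strands)
    pd.DataFrame({"position": profile.positions, "mean_density": profile.values}) \
        .to_csv(outdir / "metagene.tsv", sep="\t", index=False)


def crc_analysis(pwms: dict, genome: dict[str, str],
                 table: rose.EnhancerTable,
                 assignment: rose.SEGeneAssignment,
                 expr: pd.DataFrame,
                 basal_samples: list[str] | None = None,
                 threshold_frac: float = 0.8) -> dict:
    """CRC inference from in-memory artifacts: scan SE sequences with every
    TF's PWM, build the graph, enumerate cliques and rank core TFs.

    A TF's SEs are the is_se regions it is assigned to; its SE rank is the
    best rank among them.  Co-expression uses ``basal_samples`` (all
    samples when None).
    """
    active = set(resp.filter_active(expr))
    se_seqs: dict[str, list[tuple[str, str]]] = {tf: [] for tf in pwms}
    se_ranks: dict[str, int] = {}
    for e in table.enhancers:
        if not e.is_se:
            continue
        seq = genome[e.region.chrom][e.region.start: e.region.end]
        for gid in assignment.genes.get(e.name, []):
            if gid in pwms:
                se_seqs[gid].append((e.name, seq))
                se_ranks[gid] = min(se_ranks.get(gid, e.rank), e.rank)
    graph, hits = crc_mod.crc_from_sequences(
        se_seqs, pwms, threshold_frac=threshold_frac,
        expressed_tfs=active & set(pwms),
    )
    cliques = crc_mod.enumerate_cliques(graph)
    basal = expr[basal_samples] if basal_samples else expr
    coexpr = (crc_mod.coexpression(basal, graph.nodes)
              if graph.nodes else pd.DataFrame())
    scores = crc_mod.score_tfs(cliques, coexpr, se_ranks, graph.nodes) \
        if graph.nodes else []
    ranked = crc_mod.rank_core_tfs(scores)
    return {"graph": graph, "hits": hits, "cliques": cliques,
            "coexpression": coexpr, "scores": ranked, "se_ranks": se_ranks}


def stage_crc(config: PipelineConfig, simdir: Path, sedir: Path,
              outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pwms = {p.name: p for p in crc_mod.read_jaspar(simdir / "motifs.jaspar")}
    genome = gc.read_fasta(simdir / "genome.fa")
    table = read_enhancer_table(sedir / "se_table.tsv", "h3k27ac")
    assignment = read_assignment(sedir / "se_genes.tsv")
    expr = pd.read_csv(simdir / "expression.tsv", sep="\t", index_col=0)
    conditions = pd.read_csv(simdir / "conditions.tsv", sep="\t",
                             index_col=0)["condition"].to_dict()
    basal_cols = [s for s in expr.columns
                  if conditions.get(s, "control") == "control"]
    result = crc_analysis(pwms, genome, table, assignment, expr,
                          basal_samples=basal_cols,
                          threshold_frac=config.scan_threshold_frac)
    graph, cliques, ranked = result["graph"], result["cliques"], result["scores"]

    pd.DataFrame(
        [{"source": a, "target": b, "hits": graph.edge_count(a, b)}
         for a, b in sorted(graph.graph.edges)]
    ).to_csv(outdir / "edges.tsv", sep="\t", index=False)
    with open(outdir / "cliques.txt", "w") as fh:
        for c in cliques:
            fh.write(",".join(sorted(c)) + "\n")
    pd.DataFrame(
        [{"tf": s.tf, "clique_fraction": s.clique_fraction,
          "mean_coexpression": s.mean_coexpression, "se_rank": s.se_rank}
         for s in ranked]
    ).to_csv(outdir / "tf_scores.tsv", sep="\t", index=False)


def stage_respond(config: PipelineConfig, simdir: Path, sedir: Path,
                  outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    expr = pd.read_csv(simdir / "expression.tsv", sep="\t", index_col=0)
    conditions = pd.read_csv(simdir / "conditions.tsv", sep="\t",
                             index_col=0)["condition"].to_dict()
    table = read_enhancer_table(sedir / "se_table.tsv", "h3k27ac")
    assignment = read_assignment(sedir / "se_genes.tsv")
    se_genes = assignment.se_gene_ids(table)

    active = resp.filter_active(expr)
    groups = resp.group_by_annotation(active, {"SE": se_genes})
    fc = resp.log2fc(expr, conditions, "control", "treatment")
    fc.to_csv(outdir / "log2fc.tsv", sep="\t")

    comparison = resp.rank_test(
        fc.reindex(groups["SE"]).dropna(),
        fc.reindex(groups["none"]).dropna(),
        paired=config.paired_test, alternative="less",
    )
    basal = resp.basal_expression_by_se_class(
        expr, groups, compare=("SE", "none"),
        samples=[s for s, c in conditions.items() if c == "control"],
        alternative="greater",
    )
    payload = {
        "group_sizes": {k: len(v) for k, v in groups.items()},
        "median_log2fc": {k: float(np.median(fc.reindex(v).dropna()))
                          for k, v in groups.items() if len(v)},
        "response_test": dataclasses.asdict(comparison),
        "basal_medians": basal["medians"],
        "basal_test": dataclasses.asdict(basal["comparison"]),
    }
    with open(outdir / "response.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------

def region_recovery(called, truth) -> tuple[float, float]:
    """(precision, recall) of called regions against planted truth regions.

    A called region counts as correct when it overlaps a truth region and
    vice versa (≥ 1 bp).
    """
    if not called:
        return (float("nan"), 0.0 if truth else float("nan"))
    if not truth:
        return (0.0, float("nan"))
    tp_called = sum(any(c.overlaps(t) for t in truth) for c in called)
    tp_truth = sum(any(t.overlaps(c) for c in called) for t in truth)
    return tp_called / len(called), tp_truth / len(truth)


def _checksums(root: Path) -> dict[str, str]:
    out = {}
    for path in sorted(root.rglob("*")):
        if path.is_file() and path.suffix != ".fai":
            out[str(path.relative_to(root))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage; returns (and writes) the machine-readable summary."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    simdir, sedir = root / "sim", root / "se"
    stages = [
        ("simulate", lambda: stage_simulate(config, simdir)),
        ("call-se", lambda: stage_call_se(config, simdir, sedir)),
        ("annotate", lambda: stage_annotate(config, simdir, sedir, root / "annotate")),
        ("pol2", lambda: stage_pol2(config, simdir, root / "pol2")),
        ("crc", lambda: stage_crc(config, simdir, sedir, root / "crc")),
        ("respond", lambda: stage_respond(config, simdir, sedir, root / "respond")),
    ]
    log = []
    for name, fn in stages:
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        log.append({"stage": name, "status": "ok"})

    # summary against planted truth
    with open(simdir / "truth.json") as fh:
        truth = json.load(fh)
    table = read_enhancer_table(sedir / "se_table.tsv", "h3k27ac")
    truth_se = [gc.GenomicInterval(*r) for r in truth["se_regions"]]
    precision, recall = region_recovery(table.se_regions(), truth_se)
    with open(root / "pol2" / "pausing_index.tsv") as fh:
        pi = pd.read_csv(fh, sep="\t", index_col=0)["pausing_index"]
    with open(root / "respond" / "response.json") as fh:
        response = json.load(fh)
    tf_scores = pd.read_csv(root / "crc" / "tf_scores.tsv", sep="\t")
    summary = {
        "config_seed": config.seed,
        "n_se_called": table.n_se,
        "n_te_called": table.n_te,
        "se_precision": precision,
        "se_recall": recall,
        "mean_pausing_index": float(pi.dropna().mean()),
        "true_pausing_index": config.sim.pausing_index_true,
        "top_tfs": tf_scores["tf"].head(3).tolist(),
        "planted_crc_tfs": truth["crc_tfs"],
        "response_p": response["response_test"]["pvalue"],
        "median_log2fc": response["median_log2fc"],
        "stages": log,
    }
    summary["checksums"] = _checksums(root)
    with open(root / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
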