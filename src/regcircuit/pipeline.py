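"""Staged orchestration of the full analysis on a synthetic dataset.

Stages (dependency order): simulate -> quantify -> differential -> link ->
de -> grn -> hierarchy -> disease -> gsea -> motif. Each stage reads the
artifacts of its prerequisites from the output directory, writes TSV/JSON
artifacts, and appends a log entry with the config hash and RNG seed.
Numeric artifacts are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import cre as cre_mod
from . import disease as disease_mod
from . import expression as expr_mod
from . import grn as grn_mod
from . import io
from . import linking
from . import motifs as motifs_mod
from . import simulate as sim_mod
from .config import PipelineConfig, SimConfig, config_hash

logger = logging.getLogger(__name__)

STAGE_ORDER = [
    "simulate",
    "quantify",
    "differential",
    "link",
    "de",
    "grn",
    "hierarchy",
    "disease",
    "gsea",
    "motif",
]

STAGE_DEPS = {
    "simulate": [],
    "quantify": ["simulate"],
    "differential": ["quantify"],
    "link": ["quantify"],
    "de": ["simulate"],
    "grn": ["quantify", "de"],
    "hierarchy": ["grn"],
    "disease": ["simulate"],
    "gsea": ["de"],
    "motif": ["differential", "de"],
}

# a representative artifact per stage, used for dependency checking
STAGE_SENTINEL = {
    "simulate": "genes.bed",
    "quantify": "normalized_ATAC.tsv",
    "differential": "differential_cres.tsv",
    "link": "links_promoter.tsv",
    "de": "de_A_vs_B.tsv",
    "grn": "influence_ref_to_A.tsv",
    "hierarchy": "hierarchy_edges.tsv",
    "disease": "tf_peaks",
    "gsea": "gsea.tsv",
    "motif": "motif_enrichment.tsv",
}


class PipelineError(RuntimeError):
    pass


def _require(outdir: Path, stage: str) -> None:
    for dep in STAGE_DEPS[stage]:
        if not (outdir / STAGE_SENTINEL[dep]).exists():
            raise PipelineError(
                f"stage {stage!r} requires artifacts of stage {dep!r}; run {dep!r} first"
            )


def _log_stage(outdir: Path, stage: str, cfg, seed: int, inputs: list[Path]) -> None:
    checksums = {}
    for p in inputs:
        if p.is_file():
            checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:12]
    entry = {
        "stage": stage,
        "time": datetime.now(timezone.utc).isoformat(),
        "config_hash": config_hash(cfg),
        "seed": seed,
        "input_checksums": checksums,
    }
    with (outdir / "run_log.jsonl").open("a") as fh:
        fh.write(json.dumps(entry, sort_keys=True) + "\n")


def _weight_function(cfg: PipelineConfig) -> linking.WeightFunction:
    return linking.WeightFunction(
        full_weight_radius_bp=cfg.full_weight_radius_bp,
        half_weight_distance_bp=cfg.half_weight_distance_bp,
        max_distance_bp=cfg.enhancer_window_bp,
    )


def _marks(cfg: PipelineConfig) -> list[str]:
    return sorted(cfg.window_bp_by_mark)


def run_pipeline(
    pipe_cfg: PipelineConfig,
    sim_cfg: SimConfig,
    stages: list[str] | None = None,
    outdir: str | Path = "out",
) -> Path:
    """Run the requested stages (all by default) in dependency order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    requested = set(STAGE_ORDER if stages is None else stages)
    unknown = requested - set(STAGE_ORDER)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    for stage in STAGE_ORDER:
        if stage in requested:
            _require(outdir, stage)
            logger.info("running stage %s", stage)
            _RUNNERS[stage](pipe_cfg, sim_cfg, outdir)
            _log_stage(outdir, stage, pipe_cfg, sim_cfg.rng_seed, [])
    return outdir


# --- stage implementations -------------------------------------------------


def _stage_simulate(cfg: PipelineConfig, sim_cfg: SimConfig, outdir: Path) -> None:
    land = sim_mod.simulate_landscape(sim_cfg)
    genes, catalogue, truth = land["genes"], land["catalogue"], land["truth"]
    io.write_gene_annotation(genes, outdir / "genes.bed")
    catalogue.to_csv(outdir / "catalogue.tsv", sep="\t", index=False)
    for mark, mat in land["counts"].items():
        io.write_matrix(mat, outdir / f"counts_{mark}.tsv")
    hits = sim_mod.simulate_motif_hits(sim_cfg, truth, catalogue)
    io.write_matrix(hits, outdir / "motif_hits.tsv")
    expr = sim_mod.simulate_expression(sim_cfg, truth, genes)
    io.write_matrix(expr["counts"], outdir / "expression_counts.tsv")
    io.write_matrix(expr["tpm"], outdir / "expression_tpm.tsv")
    expr["metadata"].to_csv(outdir / "samples.tsv", sep="\t", index=False)
    peak_dir = outdir / "tf_peaks"
    peak_dir.mkdir(exist_ok=True)
    for tf, peaks in sim_mod.simulate_tf_peaks(sim_cfg, truth, catalogue, genes).items():
        peaks.to_csv(peak_dir / f"{tf}.tsv", sep="\t", index=False)
    io.write_gene_list(truth.disease_genes, outdir / "disease_genes.txt")
    io.write_json(truth.to_dict(), outdir / "ground_truth.json")


def _stage_quantify(cfg: PipelineConfig, sim_cfg: SimConfig, outdir: Path) -> None:
    for mark in _marks(cfg):
        raw = io.read_matrix(outdir / f"counts_{mark}.tsv")
        io.write_matrix(
            cre_mod.normalize_signal(raw), outdir / f"normalized_{mark}.tsv", "%.10g"
        )


def _states_of_columns(columns) -> np.ndarray:
    return np.array([c.rsplit("_", 1)[0] for c in columns])


def _stage_differential(cfg: PipelineConfig, sim_cfg: SimConfig, outdir: Path) -> None:
    tables = []
    for mark in _marks(cfg):
        if mark in sim_mod.ACTIVITY_MARKS:
            raw = io.read_matrix(outdir / f"counts_{mark}.tsv")
            states = _states_of_columns(raw.columns)
            tab = cre_mod.differential_count_test(
                raw, states, "A", "B", cfg.cre_padj_threshold, mark=mark
            )
        else:
            norm = io.read_matrix(outdir / f"normalized_{mark}.tsv")
            states = _states_of_columns(norm.columns)
            tab = cre_mod.threshold_variance_select(
                norm,
                states,
                "A",
                "B",
                quantile=cfg.variance_select_quantile,
                activity_cutoff=cfg.activity_cutoff,
                mark=mark,
            )
        tables.append(tab)
    all_tab = pd.concat(tables, ignore_index=True)
    all_tab.to_csv(outdir / "differential_cres.tsv", sep="\t", index=False)
    catalogue = pd.read_csv(outdir / "catalogue.tsv", sep="\t")
    io.write_json(
        cre_mod.summarize_differential(tables, len(catalogue)),
        outdir / "differential_summary.json",
    )


def _stage_link(cfg: PipelineConfig, sim_cfg: SimConfig, outdir: Path) -> None:
    catalogue = pd.read_csv(outdir / "catalogue.tsv", sep="\t")
    genes = io.read_gene_annotation(outdir / "genes.bed")
    links = linking.link_closest_tss(catalogue, genes, cfg.promoter_link_max_bp)
    links.to_csv(outdir / "links_promoter.tsv", sep="\t", index=False)
    wf = _weight_function(cfg)
    for mark in _marks(cfg):
        norm = io.read_matrix(outdir / f"normalized_{mark}.tsv")
        summary = linking.aggregate_enhancer_signal(catalogue, norm, genes, wf)
        io.write_matrix(summary, outdir / f"gene_signal_{mark}.tsv", "%.10g")


def _stage_de(cfg: PipelineConfig, sim_cfg: SimConfig, outdir: Path) -> None:
    counts = io.read_matrix(outdir / "expression_counts.tsv")
    genes = io.read_gene_annotation(outdir / "genes.bed")
    meta = pd.read_csv(outdir / "samples.tsv", sep="\t")
    counts = expr_mod.filter_genes(counts, genes, cfg.min_gene_counts)
    state_of = meta.set_index("sample")["state"]
    for target, source in (("A", "B"), ("A", "REF"), ("B", "REF")):
        cols = [c for c in counts.columns if state_of[c] in (target, source)]
        res = expr_mod.de_test(
            counts[cols],
            state_of[cols].to_numpy(),
            padj_threshold=cfg.de_padj_threshold,
            lfc_threshold=cfg.de_abs_log2fc_threshold,
            ref_level=source,
        )
        res.index.name = "gene"
        res.to_csv(outdir / f"de_{target}_vs_{source}.tsv", sep="\t")


def _stage_grn(cfg: PipelineConfig, sim_cfg: SimConfig, outdir: Path) -> None:
    catalogue = pd.read_csv(outdir / "catalogue.tsv", sep="\t")
    genes = io.read_gene_annotation(outdir / "genes.bed")
    hits = io.read_matrix(outdir / "motif_hits.tsv")
    atac = io.read_matrix(outdir / "normalized_ATAC.tsv")
    k27 = io.read_matrix(outdir / "normalized_H3K27ac.tsv")
    wf = _weight_function(cfg)
    states = sorted(set(_states_of_columns(atac.columns)))
    nets = {}
    for state in states:
        samples = [c for c in atac.columns if c.rsplit("_", 1)[0] == state]
        act = grn_mod.cre_state_activity(atac, k27, samples)
        nets[state] = grn_mod.build_binding_network(hits, act, catalogue, genes, wf, state)
        io.write_matrix(nets[state], outdir / f"binding_{state}.tsv", "%.10g")
    for target in ("A", "B"):
        de = pd.read_csv(outdir / f"de_{target}_vs_REF.tsv", sep="\t", index_col=0)
        infl = grn_mod.differential_influence(
            nets["REF"], nets[target], de, cfg.max_differential_edges, cfg.cre_padj_threshold
        )
        infl.to_csv(outdir / f"influence_ref_to_{target}.tsv", sep="\t", index=False)
    infl_a = pd.read_csv(outdir / "influence_ref_to_A.tsv", sep="\t")
    infl_b = pd.read_csv(outdir / "influence_ref_to_B.tsv", sep="\t")
    classes = grn_mod.classify_tfs(
        infl_a, infl_b, cfg.influence_shared_threshold, cfg.influence_low_threshold
    )
    classes.to_csv(outdir / "tf_classes.tsv", sep="\t", index=False)


def _stage_hierarchy(cfg: PipelineConfig, sim_cfg: SimConfig, outdir: Path) -> None:
    hits = io.read_matrix(outdir / "motif_hits.tsv")
    nets = {
        state: io.read_matrix(outdir / f"binding_{state}.tsv") for state in ("REF", "A", "B")
    }
    tf_ids = sorted(hits.columns)
    edges = grn_mod.classify_edge_regulation(nets["REF"], nets["A"], nets["B"], tf_ids)
    edges.to_csv(outdir / "hierarchy_edges.tsv", sep="\t", index=False)


def _stage_disease(cfg: PipelineConfig, sim_cfg: SimConfig, outdir: Path) -> None:
    genes = io.read_gene_annotation(outdir / "genes.bed")
    peak_dir = outdir / "tf_peaks"
    if not peak_dir.is_dir():
        raise PipelineError("stage 'disease' requires TF peak sets; run 'simulate' first")
    tf_peaks = {
        p.stem: pd.read_csv(p, sep="\t") for p in sorted(peak_dir.glob("*.tsv"))
    }
    disease = io.read_gene_list(outdir / "disease_genes.txt")
    wf = _weight_function(cfg)
    res = disease_mod.run_enrichment(
        tf_peaks, genes, {"disease": disease}, wf, cfg.enrichment_fdr_threshold
    )
    res.to_csv(outdir / "disease_enrichment.tsv", sep="\t", index=False)


def _stage_gsea(cfg: PipelineConfig, sim_cfg: SimConfig, outdir: Path) -> None:
    de = pd.read_csv(outdir / "de_A_vs_B.tsv", sep="\t", index_col=0)
    truth = sim_mod.GroundTruth.from_dict(io.read_json(outdir / "ground_truth.json"))
    metric = de["log2fc"].dropna()
    rows = []
    for tf in sorted(truth.tf_targets):
        members = [g for g in truth.tf_targets[tf] if g in metric.index]
        if len(members) < 2:
            continue
        res = expr_mod.preranked_gsea(
            metric, members, n_permutations=max(100, min(cfg.gsea_permutations, 1000)),
            seed=sim_cfg.rng_seed,
        )
        rows.append((f"targets_of_{tf}", res["es"], res["p"], res["direction"], res["n_hits"]))
    pd.DataFrame(rows, columns=["set", "es", "p", "direction", "n_hits"]).to_csv(
        outdir / "gsea.tsv", sep="\t", index=False
    )


def _stage_motif(cfg: PipelineConfig, sim_cfg: SimConfig, outdir: Path) -> None:
    hits = io.read_matrix(outdir / "motif_hits.tsv")
    diff = pd.read_csv(outdir / "differential_cres.tsv", sep="\t")
    variable = diff[(diff["mark"] == "ATAC") & (diff["class"] != "nonvariable")]
    classes = variable.set_index("cre")["class"]
    if classes.empty:
        raise PipelineError("no variable CREs for motif enrichment; check 'differential'")
    enr = motifs_mod.differential_motif_enrichment(hits, classes)
    enr.to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
    counts = io.read_matrix(outdir / "expression_counts.tsv")
    de = pd.read_csv(outdir / "de_A_vs_B.tsv", sep="\t", index_col=0)
    candidates = pd.DataFrame({"motif": [f"motif_{tf}" for tf in hits.columns], "tf": hits.columns})
    variability = motifs_mod.motif_variability(
        enr.assign(motif=enr["motif"].map(lambda t: f"motif_{t}"))
    )
    assigned = motifs_mod.filter_and_assign_motifs(
        candidates,
        counts.sum(axis=1),
        de["log2fc"],
        variability,
        min_counts=cfg.min_gene_counts,
    )
    assigned.to_csv(outdir / "motif_tf_map.tsv", sep="\t", index=False)


_RUNNERS = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "differential": _stage_differential,
    "link": _stage_link,
    "de": _stage_de,
    "grn": _stage_grn,
    "hierarchy": _stage_hierarchy,
    "disease": _stage_disease,
    "gsea": _stage_gsea,
    "motif": _stage_motif,
}
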