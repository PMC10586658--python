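"""Configuration objects for the pipeline and the simulator.

A single YAML file configures a full run; CLI flags override individual
fields. Configs round-trip losslessly through :func:`save_config` /
:func:`load_config`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

DEFAULT_WINDOWS = {"ATAC": 200, "H3K4me3": 2000, "H3K27ac": 2000, "H3K27me3": 5000}


@dataclass
class PipelineConfig:
    """Analysis-stage parameters.

    Defaults follow the published workflow: 200 bp ATAC windows around peak
    summits, 2 kb for H3K4me3/H3K27ac, 5 kb for H3K27me3; top 100,000 peaks
    per cell state; promoter links within 20 kb; enhancer aggregation within
    100 kb; differential-CRE padj < 0.05; DE padj <= 0.01 with |log2FC| >=
    0.58; genes with < 10 total counts dropped; shared-TF influence threshold
    0.5; top 500,000 differential network edges; enrichment FDR < 0.1.
    """

    window_bp_by_mark: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    top_n_peaks: int = 100_000
    merge_radius_bp: int = 200
    promoter_link_max_bp: int = 20_000
    enhancer_window_bp: int = 100_000
    full_weight_radius_bp: int = 2_000
    half_weight_distance_bp: int = 50_000
    cre_padj_threshold: float = 0.05
    de_padj_threshold: float = 0.01
    de_abs_log2fc_threshold: float = 0.58
    min_gene_counts: int = 10
    influence_shared_threshold: float = 0.5
    influence_low_threshold: float = 0.2
    max_differential_edges: int = 500_000
    enrichment_fdr_threshold: float = 0.1
    variance_select_quantile: float = 0.75
    activity_cutoff: float | None = None  # None -> two-class variance-minimizing split
    gsea_permutations: int = 10_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for mark, w in self.window_bp_by_mark.items():
            if w <= 0:
                raise ValueError(f"window for mark {mark!r} must be > 0, got {w}")
        for name in ("top_n_peaks", "merge_radius_bp", "promoter_link_max_bp",
                     "enhancer_window_bp", "max_differential_edges",
                     "min_gene_counts", "gsea_permutations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("cre_padj_threshold", "de_padj_threshold",
                     "enrichment_fdr_threshold", "variance_select_quantile"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("influence_shared_threshold", "influence_low_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.de_abs_log2fc_threshold < 0:
            raise ValueError("de_abs_log2fc_threshold must be >= 0")


@dataclass
class SimConfig:
    """Synthetic-dataset parameters.

    The simulator plants differential CREs per mark (split evenly between
    states), shared and state-specific TF programs, motif hits concentrated in
    each planted TF's active CREs, and excess TF binding near a designated
    disease gene list.
    """

    n_chroms: int = 2
    chrom_length_bp: int = 10_000_000
    n_genes: int = 400
    n_cres: int = 600
    n_samples_per_state: int = 4
    states: tuple = ("A", "B", "REF")
    frac_differential_cre: dict = field(
        default_factory=lambda: {"ATAC": 0.2, "H3K27ac": 0.2, "H3K4me3": 0.1, "H3K27me3": 0.1}
    )
    cre_effect_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    nb_mean_scale: float = 100.0
    n_tfs: int = 12
    n_shared_tfs: int = 3
    n_a_specific_tfs: int = 2
    n_b_specific_tfs: int = 2
    expression_effect_log2fc: float = 2.0
    motif_hit_background_rate: float = 0.02
    motif_hit_target_rate: float = 0.9
    tf_target_fanout: int = 20
    shared_tf_fanout: int = 28
    master_tf_fanout: int = 35
    n_cres_per_disease_gene: int = 3
    n_disease_genes: int = 30
    disease_binding_effect: float = 4.0
    batch_effect_log2: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.motif_hit_background_rate <= 1.0):
            raise ValueError("motif_hit_background_rate must lie in [0, 1]")
        if not (0.0 <= self.motif_hit_target_rate <= 1.0):
            raise ValueError("motif_hit_target_rate must lie in [0, 1]")
        if self.motif_hit_target_rate <= self.motif_hit_background_rate:
            raise ValueError("motif_hit_target_rate must exceed motif_hit_background_rate")
        for name, v in (("cre_effect_log2fc", self.cre_effect_log2fc),
                        ("expression_effect_log2fc", self.expression_effect_log2fc),
                        ("nb_dispersion", self.nb_dispersion),
                        ("nb_mean_scale", self.nb_mean_scale),
                        ("disease_binding_effect", self.disease_binding_effect)):
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        for name in ("n_chroms", "chrom_length_bp", "n_genes", "n_cres",
                     "n_samples_per_state", "n_tfs", "tf_target_fanout",
                     "shared_tf_fanout", "master_tf_fanout", "n_disease_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for frac in self.frac_differential_cre.values():
            if not (0.0 <= frac <= 1.0):
                raise ValueError("frac_differential_cre values must lie in [0, 1]")
        n_planted = self.n_shared_tfs + self.n_a_specific_tfs + self.n_b_specific_tfs
        if n_planted > self.n_tfs:
            raise ValueError("planted TF counts exceed n_tfs")


def _to_plain(obj):
    """Dataclass -> plain dict/list/scalar tree (YAML-safe)."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(cfg, path) -> None:
    """Serialize a config dataclass to YAML."""
    payload = {"kind": type(cfg).__name__, "fields": _to_plain(cfg)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


_KINDS = {"PipelineConfig": PipelineConfig, "SimConfig": SimConfig}


def load_config(path):
    """Load a config written by :func:`save_config` (lossless round-trip)."""
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict) or "kind" not in payload:
        raise ValueError(f"{path}: not a regcircuit config file")
    kind = payload["kind"]
    if kind not in _KINDS:
        raise ValueError(f"{path}: unknown config kind {kind!r}")
    cls = _KINDS[kind]
    fields = dict(payload["fields"])
    if "states" in fields and isinstance(fields["states"], list):
        fields["states"] = tuple(fields["states"])
    return cls(**fields)


def config_hash(cfg) -> str:
    """Stable short hash of a config, for run logging."""
    blob = json.dumps(_to_plain(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
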