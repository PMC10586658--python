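"""Synthetic two-state (+ reference) regulatory dataset with planted effects.

Generates a miniature genome with genes, a CRE catalogue carrying
negative-binomial per-mark signal counts with planted shared/differential
elements, TF expression programs with planted shared and state-specific
regulators, motif hits concentrated in each planted regulator's active CREs,
and TF peak sets with planted excess binding near a designated disease gene
list. Ground-truth labels are recorded so downstream stages can be scored.

All randomness derives from ``SimConfig.rng_seed`` (sub-streams per product,
so each generator is reproducible independently).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig

ACTIVITY_MARKS = ("ATAC", "H3K27ac")
THRESHOLD_MARKS = ("H3K4me3", "H3K27me3")

_PEAK_BG_RATE = 0.1
_PEAK_PROGRAM_RATE = 0.9
_LOW_SIGNAL_FRACTION = 0.3  # of background CREs, for the threshold marks


@dataclass
class GroundTruth:
    """Planted labels for recovery scoring."""

    cre_mark_class: dict = field(default_factory=dict)  # mark -> {cre: A-high|B-high|shared}
    tf_class: dict = field(default_factory=dict)  # tf gene -> shared|A-specific|B-specific|bystander
    tf_targets: dict = field(default_factory=dict)  # tf gene -> [target genes]
    program_cres: dict = field(default_factory=dict)  # tf gene -> [cre ids]
    master_tf: str = ""
    disease_genes: list = field(default_factory=list)
    disease_tfs: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cre_mark_class": self.cre_mark_class,
            "tf_class": self.tf_class,
            "tf_targets": self.tf_targets,
            "program_cres": self.program_cres,
            "master_tf": self.master_tf,
            "disease_genes": list(self.disease_genes),
            "disease_tfs": list(self.disease_tfs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)

    def validate(self) -> None:
        genes_known = set(self.tf_class) | {
            g for targets in self.tf_targets.values() for g in targets
        }
        for tf, targets in self.tf_targets.items():
            if tf not in self.tf_class:
                raise ValueError(f"edge source {tf} is not a labelled TF")
            for g in targets:
                if g not in genes_known:
                    raise ValueError(f"edge target {g} unknown")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with Var = mu + alpha*mu^2."""
    k = 1.0 / alpha
    mu = np.maximum(mu, 1e-12)
    return rng.negative_binomial(k, k / (k + mu))


def sample_names(cfg: SimConfig) -> dict[str, list[str]]:
    return {
        state: [f"{state}_{i + 1}" for i in range(cfg.n_samples_per_state)]
        for state in cfg.states
    }


def sample_batches(cfg: SimConfig) -> dict[str, str]:
    """Two-level batch factor crossed with state (alternating within state)."""
    out = {}
    for state, names in sample_names(cfg).items():
        for i, name in enumerate(names):
            out[name] = "b1" if i % 2 == 0 else "b2"
    return out


def simulate_landscape(cfg: SimConfig) -> dict:
    """Genome, genes, CRE catalogue, per-mark count matrices, ground truth.

    Returns ``{"genes": DataFrame, "catalogue": DataFrame,
    "counts": {mark: DataFrame}, "truth": GroundTruth}``.

    Per mark, ``round(frac_differential * n_cres)`` CREs are differential,
    split evenly between A-high and B-high by deterministic index assignment;
    planted program CREs of state-specific TFs occupy the corresponding
    differential slots of the activity marks (and are placed within the
    enhancer window of their program genes' TSSs). Counts are negative
    binomial with the favored state's mean at ``mu * 2^(+effect/2)`` and the
    other at ``mu * 2^(-effect/2)``.
    """
    rng = np.random.default_rng([cfg.rng_seed, 0])
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]

    # --- genes ---
    gene_chrom = rng.choice(len(chroms), size=cfg.n_genes)
    margin = min(50_000, cfg.chrom_length_bp // 10)
    gene_tss = rng.integers(margin, cfg.chrom_length_bp - margin, size=cfg.n_genes)
    gene_strand = rng.choice(["+", "-"], size=cfg.n_genes)
    genes = pd.DataFrame(
        {"chrom": [chroms[c] for c in gene_chrom], "tss": gene_tss, "strand": gene_strand}
    )
    genes = genes.sort_values(["chrom", "tss"], kind="stable").reset_index(drop=True)
    genes.insert(0, "gene", [f"G{i:04d}" for i in range(len(genes))])
    genes["start"] = np.where(genes["strand"] == "+", genes["tss"], genes["tss"] - 999)
    genes["end"] = np.where(genes["strand"] == "+", genes["tss"] + 1000, genes["tss"] + 1)

    # --- TF programs ---
    all_ids = genes["gene"].tolist()
    perm = rng.permutation(cfg.n_genes)
    tf_ids = [all_ids[i] for i in perm[: cfg.n_tfs]]
    n_sh, n_a, n_b = cfg.n_shared_tfs, cfg.n_a_specific_tfs, cfg.n_b_specific_tfs
    tf_class = {}
    for i, tf in enumerate(tf_ids):
        if i < n_sh:
            tf_class[tf] = "shared"
        elif i < n_sh + n_a:
            tf_class[tf] = "A-specific"
        elif i < n_sh + n_a + n_b:
            tf_class[tf] = "B-specific"
        else:
            tf_class[tf] = "bystander"
    planted = [tf for tf in tf_ids if tf_class[tf] != "bystander"]
    master = tf_ids[n_sh] if n_a > 0 else ""

    pool = [all_ids[i] for i in perm[cfg.n_tfs :]]
    tf_targets: dict[str, list[str]] = {}
    cursor = 0
    for tf in planted:
        if tf == master:
            fanout = cfg.master_tf_fanout
        elif tf_class[tf] == "shared":
            fanout = cfg.shared_tf_fanout
        else:
            fanout = cfg.tf_target_fanout
        if cursor + fanout > len(pool):
            raise ValueError("not enough non-TF genes for the requested TF fanouts")
        tf_targets[tf] = pool[cursor : cursor + fanout]
        cursor += fanout
    free_genes = pool[cursor:]
    if len(free_genes) < cfg.n_disease_genes:
        raise ValueError("not enough program-free genes for the disease list")
    disease_genes = sorted(
        [free_genes[i] for i in rng.permutation(len(free_genes))[: cfg.n_disease_genes]]
    )
    disease_tfs = [tf for tf in tf_ids if tf_class[tf] == "shared"][:1]

    # --- CRE placement (construction order encodes planted structure) ---
    tss_of = genes.set_index("gene")["tss"]
    chrom_of = genes.set_index("gene")["chrom"]
    cre_rows: list[tuple[str, int]] = []  # (chrom, summit) in construction order
    program_slots: dict[str, list[int]] = {tf: [] for tf in planted}

    def _place_near(gene: str) -> tuple[str, int]:
        offset = int(rng.integers(-15_000, 15_001))
        summit = int(np.clip(tss_of[gene] + offset, 100, cfg.chrom_length_bp - 100))
        return chrom_of[gene], summit

    order_classes = ["A-specific", "B-specific", "shared"]
    block_sizes = {}
    for klass in order_classes:
        count = 0
        for tf in planted:
            if tf_class[tf] != klass:
                continue
            for gene in [tf] + tf_targets[tf]:
                program_slots[tf].append(len(cre_rows))
                cre_rows.append(_place_near(gene))
                count += 1
        block_sizes[klass] = count
    n_program = len(cre_rows)
    # candidate binding sites near disease genes (neutral signal, no labels):
    # gives the nearest-TSS and weighted-score enrichment tests substrate
    for gene in disease_genes:
        for _ in range(cfg.n_cres_per_disease_gene):
            offset = int(rng.integers(-20_000, 20_001))
            summit = int(np.clip(tss_of[gene] + offset, 100, cfg.chrom_length_bp - 100))
            cre_rows.append((chrom_of[gene], summit))
    n_disease_cres = len(cre_rows) - n_program
    n_background = cfg.n_cres - n_program - n_disease_cres
    if n_background < 0:
        raise ValueError(
            f"n_cres={cfg.n_cres} too small for {n_program} planted program CREs "
            f"plus {n_disease_cres} disease-adjacent CREs"
        )
    bg_chrom = rng.choice(len(chroms), size=n_background)
    bg_summit = rng.integers(1_000, cfg.chrom_length_bp - 1_000, size=n_background)
    for c, s in zip(bg_chrom, bg_summit):
        cre_rows.append((chroms[c], int(s)))

    # construction-order index blocks
    a_prog = list(range(0, block_sizes["A-specific"]))
    b_prog = list(
        range(block_sizes["A-specific"], block_sizes["A-specific"] + block_sizes["B-specific"])
    )
    shared_prog = list(range(len(a_prog) + len(b_prog), n_program))
    background = list(range(n_program + n_disease_cres, cfg.n_cres))
    n_low = int(_LOW_SIGNAL_FRACTION * n_background)
    low_signal = set(background[n_background - n_low :]) if n_low else set()
    filler = [i for i in background if i not in low_signal]

    # --- per-mark differential assignment ---
    marks = list(dict.fromkeys(list(ACTIVITY_MARKS) + list(THRESHOLD_MARKS)))
    assign: dict[str, tuple[set, set]] = {}
    for mark in marks:
        frac = cfg.frac_differential_cre.get(mark, 0.0)
        n_diff = int(round(frac * cfg.n_cres))
        n_ah = n_diff // 2
        n_bh = n_diff - n_ah
        if mark in ACTIVITY_MARKS and n_diff > 0:
            if n_ah < len(a_prog) or n_bh < len(b_prog):
                raise ValueError(
                    f"frac_differential_cre[{mark}] too small to cover planted program CREs"
                )
            a_high = set(a_prog) | set(filler[: n_ah - len(a_prog)])
            used = n_ah - len(a_prog)
            b_high = set(b_prog) | set(filler[used : used + (n_bh - len(b_prog))])
        else:
            a_high = set(filler[:n_ah])
            b_high = set(filler[n_ah : n_ah + n_bh])
        assign[mark] = (a_high, b_high)

    # --- counts ---
    names = sample_names(cfg)
    up = 2.0 ** (cfg.cre_effect_log2fc / 2.0)
    dn = 2.0 ** (-cfg.cre_effect_log2fc / 2.0)
    base_mu = rng.lognormal(np.log(cfg.nb_mean_scale), 0.5, size=cfg.n_cres)
    counts_by_mark = {}
    class_by_mark: dict[str, list[str]] = {}
    prog_ref_low = set(a_prog) | set(b_prog) | set(shared_prog)
    planted_any = any(v > 0 for v in cfg.frac_differential_cre.values())
    for mark in marks:
        a_high, b_high = assign[mark]
        mu_state = {}
        for state in cfg.states:
            mu = base_mu.copy()
            if mark in THRESHOLD_MARKS and low_signal:
                idx = np.fromiter(low_signal, dtype=int)
                mu[idx] = cfg.nb_mean_scale * 0.02
            if a_high:
                idx = np.fromiter(a_high, dtype=int)
                mu[idx] *= {"A": up, "B": dn}.get(state, 1.0)
            if b_high:
                idx = np.fromiter(b_high, dtype=int)
                mu[idx] *= {"A": dn, "B": up}.get(state, 1.0)
            if mark in ACTIVITY_MARKS and planted_any:
                # program CREs are silent in the reference state and, for
                # shared programs, active in both A and B
                sp = np.fromiter(shared_prog, dtype=int) if shared_prog else None
                if sp is not None and state in ("A", "B"):
                    mu[sp] = base_mu[sp] * up
                if state == "REF" and prog_ref_low:
                    # program CREs are silent in the reference state: full
                    # effect-size suppression, not half
                    idx = np.fromiter(prog_ref_low, dtype=int)
                    mu[idx] = base_mu[idx] * dn * dn
            mu_state[state] = mu
        cols = {}
        for state in cfg.states:
            for name in names[state]:
                cols[name] = _nb_draw(rng, mu_state[state], cfg.nb_dispersion)
        counts_by_mark[mark] = pd.DataFrame(cols)
        labels = ["shared"] * cfg.n_cres
        for i in a_high:
            labels[i] = "A-high"
        for i in b_high:
            labels[i] = "B-high"
        class_by_mark[mark] = labels

    # --- catalogue: sort by coordinate, assign ids, remap construction indices ---
    cat = pd.DataFrame(cre_rows, columns=["chrom", "summit"])
    cat["construction_index"] = np.arange(cfg.n_cres)
    cat = cat.sort_values(["chrom", "summit", "construction_index"], kind="stable").reset_index(
        drop=True
    )
    cat.insert(0, "cre", [f"CRE{i:06d}" for i in range(len(cat))])
    id_of = {int(ci): cre for ci, cre in zip(cat["construction_index"], cat["cre"])}
    cat["source_states"] = "A,B"
    catalogue = cat[["cre", "chrom", "summit", "source_states"]]

    for mark in marks:
        df = counts_by_mark[mark]
        df.index = pd.Index([id_of[i] for i in range(cfg.n_cres)], name="cre")
        counts_by_mark[mark] = df.loc[catalogue["cre"]]

    truth = GroundTruth(
        cre_mark_class={
            mark: {id_of[i]: lab for i, lab in enumerate(class_by_mark[mark])}
            for mark in marks
        },
        tf_class=tf_class,
        tf_targets=tf_targets,
        program_cres={tf: sorted(id_of[i] for i in idxs) for tf, idxs in program_slots.items()},
        master_tf=master,
        disease_genes=disease_genes,
        disease_tfs=disease_tfs,
    )
    truth.validate()
    return {
        "genes": genes[["gene", "chrom", "start", "end", "strand", "tss"]],
        "catalogue": catalogue,
        "counts": counts_by_mark,
        "truth": truth,
    }


def simulate_motif_hits(cfg: SimConfig, truth: GroundTruth, catalogue: pd.DataFrame) -> pd.DataFrame:
    """0/1 CRE x TF motif-hit matrix.

    Background hits are Bernoulli(``motif_hit_background_rate``) everywhere;
    each planted TF's motif additionally hits its program CREs with
    probability ``motif_hit_target_rate``.
    """
    rng = np.random.default_rng([cfg.rng_seed, 3])
    tfs = sorted(truth.tf_class)
    hits = (
        rng.random((len(catalogue), len(tfs))) < cfg.motif_hit_background_rate
    ).astype(int)
    df = pd.DataFrame(hits, index=pd.Index(catalogue["cre"], name="cre"), columns=tfs)
    pos = {cre: i for i, cre in enumerate(catalogue["cre"])}
    for tf in sorted(truth.program_cres):
        idx = [pos[c] for c in truth.program_cres[tf]]
        add = rng.random(len(idx)) < cfg.motif_hit_target_rate
        col = df.columns.get_loc(tf)
        df.iloc[[i for i, a in zip(idx, add) if a], col] = 1
    return df


def simulate_expression(cfg: SimConfig, truth: GroundTruth, genes: pd.DataFrame) -> dict:
    """Expression counts, TPM and sample metadata over states A, B, REF.

    Planted program genes (each planted TF and its targets) have their mean
    multiplied by ``2^(+effect/2)`` in the program's active states and
    ``2^(-effect/2)`` elsewhere (A-specific: active in A; B-specific: in B;
    shared: in A and B but not REF). Bystander genes are flat. A two-level
    batch factor crossed with state adds ``batch_effect_log2`` (log2 scale) to
    the second batch.
    """
    rng = np.random.default_rng([cfg.rng_seed, 1])
    names = sample_names(cfg)
    batches = sample_batches(cfg)
    gene_ids = genes["gene"].tolist()
    base_mu = rng.lognormal(np.log(200.0), 0.8, size=len(gene_ids))

    active_states: dict[str, set] = {}
    for tf, klass in truth.tf_class.items():
        if klass == "bystander":
            continue
        states = {"A-specific": {"A"}, "B-specific": {"B"}, "shared": {"A", "B"}}[klass]
        for gene in [tf] + truth.tf_targets.get(tf, []):
            active_states[gene] = states

    up = 2.0 ** (cfg.expression_effect_log2fc / 2.0)
    dn = 2.0 ** (-cfg.expression_effect_log2fc / 2.0)
    cols = {}
    meta_rows = []
    for state in cfg.states:
        mult = np.ones(len(gene_ids))
        for i, gene in enumerate(gene_ids):
            if gene in active_states:
                mult[i] = up if state in active_states[gene] else dn
        for name in names[state]:
            batch = batches[name]
            bmult = 2.0**cfg.batch_effect_log2 if batch == "b2" else 1.0
            cols[name] = _nb_draw(rng, base_mu * mult * bmult, cfg.nb_dispersion)
            meta_rows.append((name, state, batch))
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene"))
    tpm = counts / counts.sum(axis=0) * 1e6
    metadata = pd.DataFrame(meta_rows, columns=["sample", "state", "batch"])
    return {"counts": counts, "tpm": tpm, "metadata": metadata}


def simulate_tf_peaks(
    cfg: SimConfig, truth: GroundTruth, catalogue: pd.DataFrame, genes: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Per-TF peak sets with intensities.

    Each TF peaks at its program CREs with high probability and at background
    CREs with a low rate. For designated disease TFs, CREs within the enhancer
    window (100 kb) of a disease gene TSS get both a placement probability and
    an intensity multiplied by ``disease_binding_effect`` (an effect of 1 is
    the exact null).
    """
    rng = np.random.default_rng([cfg.rng_seed, 2])
    tss_by_chrom = {
        chrom: np.sort(sub["tss"].to_numpy())
        for chrom, sub in genes[genes["gene"].isin(truth.disease_genes)].groupby("chrom")
    }
    summits = catalogue["summit"].to_numpy()
    chroms_arr = catalogue["chrom"].to_numpy()
    near_disease = np.zeros(len(catalogue), dtype=bool)
    for chrom, tss in tss_by_chrom.items():
        on = chroms_arr == chrom
        if not on.any():
            continue
        s = summits[on]
        j = np.searchsorted(tss, s)
        dist = np.full(s.shape, np.inf)
        left_ok = j > 0
        dist[left_ok] = np.abs(s[left_ok] - tss[j[left_ok] - 1])
        right_ok = j < len(tss)
        dist[right_ok] = np.minimum(dist[right_ok], np.abs(tss[j[right_ok]] - s[right_ok]))
        near_disease[on] = dist <= 100_000

    out: dict[str, pd.DataFrame] = {}
    for tf in sorted(truth.tf_class):
        prob = np.full(len(catalogue), _PEAK_BG_RATE)
        scale = np.ones(len(catalogue))
        if tf in truth.program_cres:
            prog = catalogue["cre"].isin(truth.program_cres[tf]).to_numpy()
            prob[prog] = _PEAK_PROGRAM_RATE
        if tf in truth.disease_tfs:
            prob[near_disease] = np.minimum(
                prob[near_disease] * cfg.disease_binding_effect, 1.0
            )
            scale[near_disease] = cfg.disease_binding_effect
        placed = rng.random(len(catalogue)) < prob
        intensity = rng.lognormal(np.log(50.0), 0.5, size=len(catalogue)) * scale
        peaks = pd.DataFrame(
            {
                "chrom": chroms_arr[placed],
                "summit": summits[placed],
                "intensity": intensity[placed],
            }
        ).reset_index(drop=True)
        out[tf] = peaks
    return out
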