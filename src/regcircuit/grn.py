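"""TF binding networks, differential influence and TF/edge classification.

A transparent binding proxy replaces trained TF-binding models: per CRE, the
proxy is motif presence times min-max-scaled CRE activity (mean of normalized
ATAC and H3K27ac signal in the state); per TF-gene pair, the binding score is
the max-scaled distance-weighted sum of the proxy over CREs within the
enhancer window of the gene's TSS. The comparison design on top (reference-
anchored differential networks, the 0.5 shared-TF rule, delta-binding
hierarchy labels) is the analysis of interest.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .linking import WeightFunction, _pairs_within_window, distance_weight

logger = logging.getLogger(__name__)


def cre_state_activity(
    atac: pd.DataFrame, k27ac: pd.DataFrame, samples: list[str]
) -> pd.Series:
    """Min-max-scaled per-CRE activity: mean of the two marks' state means."""
    common = atac.index.intersection(k27ac.index)
    a = atac.loc[common, [s for s in samples if s in atac.columns]].mean(axis=1)
    k = k27ac.loc[common, [s for s in samples if s in k27ac.columns]].mean(axis=1)
    act = (a + k) / 2.0
    lo, hi = act.min(), act.max()
    if hi > lo:
        act = (act - lo) / (hi - lo)
    else:
        act = act * 0.0
    return act


def build_binding_network(
    motif_hits: pd.DataFrame,
    activity: pd.Series,
    catalogue: pd.DataFrame,
    genes: pd.DataFrame,
    wf: WeightFunction,
    state: str = "",
) -> pd.DataFrame:
    """Build a TF-to-gene binding score matrix for one cell state.

    Parameters
    ----------
    motif_hits : DataFrame
        0/1 matrix, rows = CRE ids (must be catalogue ids), columns = TF ids.
    activity : Series
        Per-CRE activity in this state, indexed by CRE id.
    catalogue, genes : DataFrames with (cre, chrom, summit) / (gene, chrom, tss).
    wf : distance weight function (window = wf.max_distance_bp).

    Returns
    -------
    DataFrame indexed by gene, columns = TFs, values = binding scores scaled
    so the maximum edge in the network is 1 (all-zero networks stay zero).
    TFs absent from the motif matrix simply have no column.
    """
    unknown = motif_hits.index.difference(catalogue["cre"])
    if len(unknown):
        raise ValueError(f"motif matrix rows not in catalogue: {list(unknown[:5])}")
    pairs = _pairs_within_window(catalogue, genes, wf.max_distance_bp)
    B = pd.DataFrame(
        0.0, index=pd.Index(genes["gene"], name="gene"), columns=list(motif_hits.columns)
    )
    if not pairs.empty:
        act = activity.reindex(motif_hits.index).fillna(0.0).to_numpy()
        proxy = motif_hits.to_numpy(dtype=float) * act[:, None]  # CRE x TF
        cre_pos = pd.Series(np.arange(len(motif_hits)), index=motif_hits.index)
        pairs = pairs[pairs["cre"].isin(motif_hits.index)]
        w = distance_weight(pairs["abs_distance"].to_numpy(), wf)
        rows = pairs["gene"].map(
            pd.Series(np.arange(len(B)), index=B.index)
        ).to_numpy()
        cols = cre_pos[pairs["cre"]].to_numpy()
        raw = np.zeros((len(B), proxy.shape[1]))
        np.add.at(raw, rows, proxy[cols] * w[:, None])
        B.iloc[:, :] = raw
    mx = B.to_numpy().max() if B.size else 0.0
    if mx > 0:
        B /= mx
    B.attrs["state"] = state
    return B


def differential_influence(
    net_source: pd.DataFrame,
    net_target: pd.DataFrame,
    de: pd.DataFrame,
    max_edges: int = 500_000,
    de_padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Score TFs by how strongly their gained edges point at up-regulated genes.

    Edge differential score = max(0, B_target - B_source); the top
    ``max_edges`` edges are kept. Each TF's raw influence is the sum over its
    kept edges of edge score times max(0, target-state log2FC) over genes
    significant at ``de_padj_threshold``; influence is raw / max(raw) so the
    top TF scores 1.

    ``de`` must have gene-indexed columns ``log2fc`` and ``padj`` computed
    target-vs-source.

    Returns a DataFrame ``(tf, influence, n_targets)`` sorted by descending
    influence (ties by tf id).
    """
    if max_edges < 1:
        raise ValueError("max_edges must be >= 1")
    genes_common = net_source.index.union(net_target.index)
    tfs = net_source.columns.union(net_target.columns)
    Bs = net_source.reindex(index=genes_common, columns=tfs).fillna(0.0).to_numpy()
    Bt = net_target.reindex(index=genes_common, columns=tfs).fillna(0.0).to_numpy()
    diff = np.maximum(Bt - Bs, 0.0)

    if diff.size > max_edges:
        flat = diff.ravel()
        order = np.argsort(-flat, kind="stable")
        kept_mask = np.zeros(flat.size, dtype=bool)
        kept_mask[order[:max_edges]] = True
        diff = np.where(kept_mask.reshape(diff.shape), diff, 0.0)

    sig = de.reindex(genes_common)
    weight = np.where(
        (sig["padj"].to_numpy() < de_padj_threshold),
        np.maximum(sig["log2fc"].to_numpy(), 0.0),
        0.0,
    )
    weight = np.nan_to_num(weight, nan=0.0)
    if not np.any(weight > 0):
        logger.warning("no significantly up-regulated genes: all influences 0")
    contrib = diff * weight[:, None]
    raw = contrib.sum(axis=0)
    mx = raw.max() if raw.size else 0.0
    influence = raw / mx if mx > 0 else raw
    n_targets = (contrib > 0).sum(axis=0)
    out = pd.DataFrame({"tf": tfs, "influence": influence, "n_targets": n_targets})
    return (
        out.sort_values(["influence", "tf"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )


def classify_tfs(
    infl_ref_a: pd.DataFrame,
    infl_ref_b: pd.DataFrame,
    shared_threshold: float = 0.5,
    low_threshold: float = 0.2,
    state_a: str = "A",
    state_b: str = "B",
) -> pd.DataFrame:
    """Classify TFs as shared, state-specific or neither from two influence runs.

    Shared: influence > ``shared_threshold`` in both reference-anchored
    comparisons. ``state_a``-specific: above threshold toward A and at most
    ``low_threshold`` (low or undetected) toward B; symmetrically for B.
    Missing TFs score 0.
    """
    a = infl_ref_a.set_index("tf")["influence"]
    b = infl_ref_b.set_index("tf")["influence"]
    tfs = sorted(a.index.union(b.index))
    a = a.reindex(tfs).fillna(0.0)
    b = b.reindex(tfs).fillna(0.0)
    labels = []
    for tf in tfs:
        ia, ib = a[tf], b[tf]
        if ia > shared_threshold and ib > shared_threshold:
            labels.append("shared-epithelial")
        elif ia > shared_threshold and ib <= low_threshold:
            labels.append(f"{state_a}-specific")
        elif ib > shared_threshold and ia <= low_threshold:
            labels.append(f"{state_b}-specific")
        else:
            labels.append("neither")
    return pd.DataFrame(
        {"tf": tfs, "influence_ref_a": a.to_numpy(), "influence_ref_b": b.to_numpy(), "class": labels}
    )


def classify_edge_regulation(
    net_ref: pd.DataFrame,
    net_a: pd.DataFrame,
    net_b: pd.DataFrame,
    tf_ids: list[str],
    state_a: str = "A",
    state_b: str = "B",
) -> pd.DataFrame:
    """Label TF-to-TF regulatory edges as shared or state-specific.

    For each TF -> target-TF edge present in at least one network (missing
    scores are 0): ``dRA = B_A - B_REF``, ``dRB = B_B - B_REF``, direct
    ``d = B_A - B_B``. If ``mean(dRA, dRB) >= |d|`` (or ``d == 0``) the edge
    is shared; otherwise it is A-specific when ``d > 0`` and B-specific when
    ``d < 0``. Expression of the TFs themselves plays no role.
    """
    tf_genes = [t for t in tf_ids]
    tfs = sorted(set(net_ref.columns) | set(net_a.columns) | set(net_b.columns))
    rows = []
    ref = net_ref.reindex(index=tf_genes, columns=tfs).fillna(0.0)
    na = net_a.reindex(index=tf_genes, columns=tfs).fillna(0.0)
    nb = net_b.reindex(index=tf_genes, columns=tfs).fillna(0.0)
    for tf in tfs:
        for target in tf_genes:
            b_ref, b_a, b_b = ref.at[target, tf], na.at[target, tf], nb.at[target, tf]
            if b_ref == 0.0 and b_a == 0.0 and b_b == 0.0:
                continue
            d_ra = b_a - b_ref
            d_rb = b_b - b_ref
            direct = b_a - b_b
            mean_ref = (d_ra + d_rb) / 2.0
            if direct == 0.0 or mean_ref >= abs(direct):
                label = "shared"
            elif direct > 0:
                label = f"{state_a}-specific"
            else:
                label = f"{state_b}-specific"
            rows.append((tf, target, d_ra, d_rb, direct, label))
    return pd.DataFrame(
        rows,
        columns=["tf", "target", "delta_ref_a", "delta_ref_b", "delta_direct", "label"],
    )
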