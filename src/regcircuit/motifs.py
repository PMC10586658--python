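"""Motif-to-TF assignment and differential motif enrichment across CRE classes.

Enrichment of a motif in a CRE class is a signed z score from the
hypergeometric null (motif-bearing CREs drawn without replacement from the
variable-CRE pool); the ensemble motif-activity method used upstream in the
original workflow is deliberately replaced by this single transparent
statistic, with matching outputs (z per class, percent of class CREs carrying
the motif, TF expression ratio).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def differential_motif_enrichment(
    hits: pd.DataFrame, cre_classes: pd.Series
) -> pd.DataFrame:
    """Hypergeometric z enrichment of each motif in each CRE class.

    Parameters
    ----------
    hits : DataFrame
        0/1 matrix, rows = CRE ids, columns = motif ids. Only rows present in
        ``cre_classes`` (the variable CREs) are used.
    cre_classes : Series
        CRE id -> class label; the labels partition the variable CREs.

    Returns
    -------
    Long DataFrame ``(motif, cre_class, z, pct_cres, n_hits_in_class)``.
    z = (k - n*K/N) / sqrt(n*K/N * (1-K/N) * (N-n)/(N-1)) with N the number
    of variable CREs, K the motif's total hits among them, n the class size
    and k the hits in the class; pct_cres = 100*k/n.
    """
    common = hits.index.intersection(cre_classes.index)
    sub = hits.loc[common].astype(float)
    classes = cre_classes.loc[common]
    N = len(sub)
    if N == 0:
        raise ValueError("no variable CREs shared between hits and classes")
    K = sub.sum(axis=0)
    rows = []
    for label in sorted(classes.unique()):
        members = classes.index[classes == label]
        n = len(members)
        if n == 0:
            logger.warning("empty CRE class %r skipped", label)
            continue
        k = sub.loc[members].sum(axis=0)
        mean = n * K / N
        with np.errstate(divide="ignore", invalid="ignore"):
            var = n * (K / N) * (1 - K / N) * (N - n) / max(N - 1, 1)
            z = (k - mean) / np.sqrt(var)
        z = z.replace([np.inf, -np.inf], 0.0).fillna(0.0)
        for motif in sub.columns:
            rows.append((motif, label, float(z[motif]), 100.0 * k[motif] / n, int(k[motif])))
    return pd.DataFrame(rows, columns=["motif", "cre_class", "z", "pct_cres", "n_hits_in_class"])


def motif_variability(enrichment: pd.DataFrame) -> pd.Series:
    """Variance of a motif's class-wise z scores (how class-discriminating it is)."""
    return enrichment.groupby("motif")["z"].var(ddof=0).fillna(0.0)


def filter_and_assign_motifs(
    candidates: pd.DataFrame,
    tf_total_counts: pd.Series,
    tf_log2fc: pd.Series,
    variability: pd.Series,
    min_counts: int = 10,
) -> pd.DataFrame:
    """Resolve a many-to-many motif/TF candidate map to a one-to-one map.

    Rules: TFs with total expression counts below ``min_counts`` are dropped;
    a motif shared by several TFs goes to the TF with the largest expression
    |log2FC|; a TF with several motifs keeps its most variable motif. Ties
    break lexicographically (smaller id wins).

    Parameters
    ----------
    candidates : DataFrame with columns ``motif, tf`` (possibly many-to-many).
    tf_total_counts : TF id -> total expression counts across states.
    tf_log2fc : TF id -> between-state expression log2FC (missing -> 0).
    variability : motif id -> cross-class enrichment variability (missing -> 0).

    Returns
    -------
    DataFrame ``(motif, tf, tf_log2fc, variability)`` — at most one row per
    motif and per TF.
    """
    cand = candidates[["motif", "tf"]].drop_duplicates().copy()
    expressed = tf_total_counts[tf_total_counts >= min_counts].index
    cand = cand[cand["tf"].isin(expressed)]
    if cand.empty:
        return pd.DataFrame(columns=["motif", "tf", "tf_log2fc", "variability"])
    cand["abs_lfc"] = cand["tf"].map(tf_log2fc).fillna(0.0).abs()
    cand["variability"] = cand["motif"].map(variability).fillna(0.0)

    # motif -> single TF: most differential TF, ties to smaller id
    cand = cand.sort_values(["motif", "abs_lfc", "tf"], ascending=[True, False, True], kind="stable")
    cand = cand.groupby("motif", as_index=False).head(1)
    # TF -> single motif: most variable motif, ties to smaller id
    cand = cand.sort_values(["tf", "variability", "motif"], ascending=[True, False, True], kind="stable")
    cand = cand.groupby("tf", as_index=False).head(1)

    out = cand.rename(columns={"abs_lfc": "tf_abs_log2fc"})
    out["tf_log2fc"] = out["tf"].map(tf_log2fc).fillna(0.0)
    return (
        out[["motif", "tf", "tf_log2fc", "variability"]]
        .sort_values("motif", kind="stable")
        .reset_index(drop=True)
    )
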