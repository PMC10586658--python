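"""Differential expression, batch removal for visualization, preranked GSEA."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .nbtest import nb_wald_glm, nb_wald_two_group

logger = logging.getLogger(__name__)

_SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


def filter_genes(
    counts: pd.DataFrame, annotation: pd.DataFrame, min_counts: int = 10
) -> pd.DataFrame:
    """Drop sex-chromosome genes and rows with total counts below ``min_counts``.

    Genes absent from the annotation are kept (no chromosome to exclude them
    by). Idempotent.
    """
    chrom = annotation.set_index("gene")["chrom"]
    on_sex = counts.index.map(lambda g: chrom.get(g) in _SEX_CHROMS)
    keep = ~np.asarray(on_sex, dtype=bool) & (counts.sum(axis=1) >= min_counts)
    return counts.loc[keep]


def de_test(
    counts: pd.DataFrame,
    condition: list[str] | np.ndarray,
    batch: list[str] | np.ndarray | None = None,
    padj_threshold: float = 0.01,
    lfc_threshold: float = 0.58,
    ref_level: str | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald differential expression with the standard thresholds.

    log2FC is test level over ``ref_level``. A gene is classed
    ``<level>-high`` only when padj <= ``padj_threshold`` AND |log2FC| >=
    ``lfc_threshold``; otherwise ``ns``. When ``batch`` is given it enters the
    model as a covariate (per-gene GLM fit).
    """
    if batch is not None:
        res = nb_wald_glm(counts, condition, batch, ref_level=ref_level)
    else:
        res = nb_wald_two_group(counts, condition, ref_level=ref_level)
    test_level = res.attrs["test_level"]
    ref = res.attrs["ref_level"]
    sig = (res["padj"] <= padj_threshold) & (res["log2fc"].abs() >= lfc_threshold)
    cls = np.where(
        sig & (res["log2fc"] > 0),
        f"{test_level}-high",
        np.where(sig & (res["log2fc"] < 0), f"{ref}-high", "ns"),
    )
    out = res[["base_mean", "log2fc", "p", "padj"]].copy()
    out["class"] = cls
    out.attrs.update(res.attrs)
    return out


def remove_batch_for_visualization(
    matrix: pd.DataFrame,
    condition: list[str] | np.ndarray,
    batch: list[str] | np.ndarray,
) -> pd.DataFrame:
    """Least-squares removal of an additive batch factor from a log-scale matrix.

    Fits, per gene, ``y = condition + batch`` (additive linear model) and
    subtracts the estimated batch component. Refitting the adjusted matrix
    with the same design leaves the condition coefficients unchanged and the
    batch coefficients at zero. Confounded designs raise.
    """
    condition = np.asarray(condition)
    batch = np.asarray(batch)
    n = matrix.shape[1]
    if len(condition) != n or len(batch) != n:
        raise ValueError("condition/batch length must match the number of columns")
    cond_levels = sorted(set(condition.tolist()))
    batch_levels = sorted(set(batch.tolist()))
    X_cond = [np.ones(n)] + [(condition == lev).astype(float) for lev in cond_levels[1:]]
    X_batch = [(batch == lev).astype(float) for lev in batch_levels[1:]]
    X = np.column_stack(X_cond + X_batch)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("condition and batch are confounded (design not full rank)")
    Y = matrix.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    n_cond = len(X_cond)
    if X_batch:
        Xb = np.column_stack(X_batch)
        adjusted = Y - Xb @ beta[n_cond:]
    else:
        adjusted = Y
    return pd.DataFrame(adjusted.T, index=matrix.index, columns=matrix.columns)


def _running_es(weights: np.ndarray, is_hit: np.ndarray) -> float:
    """Signed enrichment score of one ranked membership vector."""
    n = len(weights)
    n_hit = int(is_hit.sum())
    n_miss = n - n_hit
    hit_w = np.where(is_hit, weights, 0.0)
    total = hit_w.sum()
    if total <= 0:
        hit_w = is_hit.astype(float)
        total = float(n_hit)
    p_hit = np.cumsum(hit_w) / total
    p_miss = np.cumsum(~is_hit) / max(n_miss, 1)
    running = p_hit - p_miss
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def preranked_gsea(
    metric: pd.Series,
    gene_set: list[str] | set[str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Weighted Kolmogorov-Smirnov preranked gene-set enrichment.

    Genes are ranked by ``metric`` descending (ties by gene id for
    determinism); the running sum gains ``|metric|`` (exponent 1, normalized)
    at set members and loses ``1/(N - N_hit)`` elsewhere; ES is the extreme
    deviation. The permutation null shuffles set membership over gene labels;
    ``p = (1 + #{|ES_perm| >= |ES|}) / (1 + n_permutations)``.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    members = set(gene_set) & set(metric.index)
    if not members:
        raise ValueError("gene set does not intersect the ranked universe")
    ranked = metric.sort_index().sort_values(ascending=False, kind="stable")
    weights = np.abs(ranked.to_numpy(dtype=float))
    is_hit = ranked.index.isin(members)
    n = len(ranked)
    n_hit = int(is_hit.sum())
    if n_hit == n:
        raise ValueError("gene set covers the whole universe")
    es = _running_es(weights, is_hit)

    rng = np.random.default_rng(seed)
    # vectorized permutations: random membership masks, shared weight vector
    base = np.zeros(n, dtype=bool)
    base[:n_hit] = True
    count_ge = 0
    block = 200
    for start in range(0, n_permutations, block):
        b = min(block, n_permutations - start)
        masks = np.tile(base, (b, 1))
        masks = rng.permuted(masks, axis=1)
        hit_w = masks * weights[None, :]
        totals = hit_w.sum(axis=1)
        degenerate = totals <= 0
        if degenerate.any():
            hit_w[degenerate] = masks[degenerate].astype(float)
            totals = np.where(degenerate, float(n_hit), totals)
        p_hit = np.cumsum(hit_w, axis=1) / totals[:, None]
        p_miss = np.cumsum(~masks, axis=1) / (n - n_hit)
        running = p_hit - p_miss
        idx = np.argmax(np.abs(running), axis=1)
        es_perm = running[np.arange(b), idx]
        count_ge += int(np.sum(np.abs(es_perm) >= abs(es)))
    p = (1 + count_ge) / (1 + n_permutations)
    return {
        "es": es,
        "p": p,
        "direction": "up" if es >= 0 else "down",
        "n_hits": n_hit,
    }
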