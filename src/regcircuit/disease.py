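"""TF-binding disease-gene enrichment.

Two statistics over a TF's genome-wide binding profile versus a disease gene
list: a one-sided Mann-Whitney U test on distance-weighted per-gene binding
scores (hypothesis: disease genes are bound more), and a one-sided Fisher
exact test on the 2x2 table of nearest-TSS peak assignment (mapped vs not,
disease vs rest). FDR is controlled per test family across all TF x list
pairs of a run.
"""

from __future__ import annotations

import logging
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .cre import quantile_normalize
from .linking import WeightFunction, _pairs_within_window, distance_weight, link_closest_tss
from .nbtest import bh_adjust

logger = logging.getLogger(__name__)

_EXACT_N_MAX = 50


def score_tf_binding(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    wf: WeightFunction,
) -> pd.DataFrame:
    """Distance-weighted per-gene binding score for one TF.

    Parameters
    ----------
    peaks : DataFrame
        Columns ``chrom, summit`` plus one or more intensity columns (>= 0).
        Intensities are log10(x+1)-transformed, quantile-normalized across
        replicate columns when more than one is present, then averaged.
    genes : DataFrame with ``gene, chrom, tss``.
    wf : distance weight; peaks beyond ``wf.max_distance_bp`` contribute 0.

    Returns
    -------
    DataFrame indexed by gene with columns ``score`` (sum of w(|TSS-summit|)
    * normalized intensity; 0 when no peak is in range) and ``n_peaks``.
    """
    out = pd.DataFrame(
        {"score": 0.0, "n_peaks": 0}, index=pd.Index(genes["gene"], name="gene")
    )
    if peaks.empty:
        return out
    intensity_cols = [c for c in peaks.columns if c not in ("chrom", "summit")]
    if not intensity_cols:
        raise ValueError("peaks need at least one intensity column")
    vals = np.log10(peaks[intensity_cols].to_numpy(dtype=float) + 1.0)
    if len(intensity_cols) > 1:
        vals = quantile_normalize(pd.DataFrame(vals)).to_numpy()
    norm = vals.mean(axis=1)

    peak_cat = peaks[["chrom", "summit"]].copy()
    peak_cat["cre"] = [f"pk{i}" for i in range(len(peaks))]
    pairs = _pairs_within_window(peak_cat, genes, wf.max_distance_bp)
    if pairs.empty:
        return out
    w = distance_weight(pairs["abs_distance"].to_numpy(), wf)
    idx = pairs["cre"].str.slice(2).astype(int).to_numpy()
    contrib = pd.DataFrame({"gene": pairs["gene"], "val": w * norm[idx]})
    summed = contrib.groupby("gene")["val"].sum()
    counts = contrib.groupby("gene").size()
    out.loc[summed.index, "score"] = summed
    out.loc[counts.index, "n_peaks"] = counts
    return out


def _exact_mw_greater(x: np.ndarray, y: np.ndarray) -> float:
    """Exact one-sided (x greater) Mann-Whitney p with mid-rank ties.

    Counts, by dynamic programming over distinct pooled values, the subsets of
    size ``len(x)`` whose rank sum is at least the observed one; exact for any
    tie pattern. Doubled mid-ranks keep the arithmetic integral.
    """
    pooled = np.concatenate([x, y])
    ranks2 = np.round(2.0 * stats.rankdata(pooled)).astype(np.int64)
    n1, n = len(x), len(pooled)
    obs2 = int(ranks2[:n1].sum())
    values, counts = np.unique(pooled, return_counts=True)
    rank2_of_value = {}
    pos = 0
    for v, c in zip(values, counts):
        rank2_of_value[v] = 2 * pos + c + 1  # doubled mid-rank
        pos += c
    max_s = int(ranks2.sum())
    dp = np.zeros((n1 + 1, max_s + 1))
    dp[0, 0] = 1.0
    for v, c in zip(values, counts):
        r2 = rank2_of_value[v]
        new = np.zeros_like(dp)
        for k in range(0, c + 1):
            ways = comb(c, k)
            shift = k * r2
            if shift > max_s:
                continue
            kmax = n1 - k
            if kmax < 0:
                continue
            new[k:, shift:] += ways * dp[: n1 + 1 - k, : max_s + 1 - shift]
        dp = new
    total = comb(n, n1)
    tail = dp[n1, obs2:].sum()
    return float(tail / total)


def mannwhitney_enrichment(
    scores: pd.Series, disease: list[str] | set[str]
) -> dict:
    """One-sided Mann-Whitney U test: disease genes bound more than the rest.

    ``scores`` is a gene-indexed Series of binding scores over the whole
    universe. Disease genes missing from the universe are dropped with a
    warning; at least 2 must remain. Exact (tie-aware) enumeration is used for
    n1 + n2 <= 50, else a tie-corrected normal approximation with continuity
    correction.

    Returns ``{"statistic": U, "p": ...,"n_disease": ..., "n_background": ...}``.
    """
    disease = set(disease)
    present = sorted(disease & set(scores.index))
    missing = disease - set(present)
    if missing:
        logger.warning("%d disease genes absent from the scored universe; dropped", len(missing))
    if len(present) < 2:
        raise ValueError("need >= 2 disease genes present in the scored universe")
    is_dis = scores.index.isin(present)
    x = scores.to_numpy(dtype=float)[is_dis]
    y = scores.to_numpy(dtype=float)[~is_dis]
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_stat = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if n1 + n2 <= _EXACT_N_MAX:
        p = _exact_mw_greater(x, y)
    else:
        n = n1 + n2
        mean_u = n1 * n2 / 2.0
        _, t_counts = np.unique(np.concatenate([x, y]), return_counts=True)
        tie_term = float(np.sum(t_counts**3 - t_counts)) / (n * (n - 1))
        var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var_u <= 0:
            p = 1.0
        else:
            z = (u_stat - mean_u - 0.5) / np.sqrt(var_u)
            p = float(stats.norm.sf(z))
    return {
        "statistic": u_stat,
        "p": min(max(p, np.nextafter(0, 1)), 1.0),
        "n_disease": n1,
        "n_background": n2,
    }


def fisher_exact_greater(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test of a 2x2 table.

    Table rows are (group of interest, rest), columns (mapped, unmapped).
    Returns ``(odds_ratio, p)`` with p the upper hypergeometric tail
    P(X >= a | N, a+b, a+c) and a Haldane 0.5 correction on the odds ratio
    when any cell is zero.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    n_total = a + b + c + d
    p = float(stats.hypergeom.sf(a - 1, n_total, a + b, a + c))
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return float(orr), min(max(p, np.nextafter(0, 1)), 1.0)


def fisher_nearest_enrichment(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    disease: list[str] | set[str],
    max_bp: int | None = None,
) -> dict:
    """One-sided Fisher exact test on nearest-TSS peak assignment.

    Each peak is assigned to its single nearest TSS (unlimited distance unless
    ``max_bp`` caps it); a gene is mapped when it receives >= 1 peak. The 2x2
    table (disease vs rest) x (mapped vs not) is tested one-sided toward
    enrichment with the hypergeometric tail. The odds ratio uses a Haldane 0.5
    correction when any cell is zero; when every gene is mapped the odds ratio
    is undefined and p = 1.
    """
    disease = set(disease)
    present = disease & set(genes["gene"])
    if len(present) < len(disease):
        logger.warning("%d disease genes absent from annotation; dropped", len(disease) - len(present))
    if not present:
        raise ValueError("no disease genes present in the gene annotation")
    if peaks.empty:
        mapped: set = set()
    else:
        peak_cat = peaks[["chrom", "summit"]].copy()
        peak_cat["cre"] = [f"pk{i}" for i in range(len(peaks))]
        cap = max_bp if max_bp is not None else int(1e15)
        links = link_closest_tss(peak_cat, genes, max_bp=cap)
        mapped = set(links["gene"])
    universe = set(genes["gene"])
    rest = universe - present
    a = len(present & mapped)
    b = len(present) - a
    c = len(rest & mapped)
    d = len(rest) - c
    if b + d == 0:  # every gene mapped
        return {"odds_ratio": float("nan"), "p": 1.0, "table": (a, b, c, d), "or_undefined": True}
    orr, p = fisher_exact_greater(a, b, c, d)
    return {"odds_ratio": orr, "p": p, "table": (a, b, c, d), "or_undefined": False}


def bh_fdr(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR with enforced monotonicity."""
    return bh_adjust(np.asarray(p_values, dtype=float))


def run_enrichment(
    tf_peaks: dict[str, pd.DataFrame],
    genes: pd.DataFrame,
    gene_lists: dict[str, list[str]],
    wf: WeightFunction,
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Evaluate every TF x gene-list pair with both tests and joint FDR.

    FDR is adjusted within each test family (all pairs of the run). The top 5
    most-bound disease genes (by descending binding score, ties by gene id)
    accompany each row.

    Returns a DataFrame with columns ``tf, list, test, statistic, p, fdr,
    significant, top_bound_genes``.
    """
    rows = []
    score_cache = {
        tf: score_tf_binding(peaks, genes, wf) for tf, peaks in sorted(tf_peaks.items())
    }
    for tf in sorted(tf_peaks):
        scores = score_cache[tf]
        for list_name in sorted(gene_lists):
            members = gene_lists[list_name]
            present = sorted(set(members) & set(scores.index))
            top5 = (
                scores.loc[present]
                .reset_index()
                .sort_values(["score", "gene"], ascending=[False, True], kind="stable")
                .head(5)["gene"]
                .tolist()
            )
            mw = mannwhitney_enrichment(scores["score"], members)
            rows.append(
                (tf, list_name, "mannwhitney", mw["statistic"], mw["p"], top5)
            )
            fe = fisher_nearest_enrichment(tf_peaks[tf], genes, members)
            rows.append(
                (tf, list_name, "fisher", fe["odds_ratio"], fe["p"], top5)
            )
    out = pd.DataFrame(
        rows, columns=["tf", "list", "test", "statistic", "p", "top_bound_genes"]
    )
    out["fdr"] = np.nan
    for test in ("mannwhitney", "fisher"):
        mask = out["test"] == test
        out.loc[mask, "fdr"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    out["top_bound_genes"] = out["top_bound_genes"].map(";".join)
    return out[["tf", "list", "test", "statistic", "p", "fdr", "significant", "top_bound_genes"]]
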