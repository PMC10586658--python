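"""CRE catalogue construction and differential epigenetic-state calls.

The catalogue merges the top-N accessibility peaks of each cell state by
summit proximity. Per-mark signal is counted in mark-specific windows around
each merged summit, normalized (log10 + quantile), and classified between the
two cell states: a count-based NB Wald test for ATAC/H3K27ac, and a two-step
activity-plus-variability selection for H3K4me3/H3K27me3.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import PeakRecord
from .nbtest import bh_adjust, nb_wald_two_group

logger = logging.getLogger(__name__)

_LOG10_2 = np.log10(2.0)


def merge_top_peaks(
    peaks_by_state: dict[str, list[PeakRecord]],
    top_n: int = 100_000,
    merge_radius: int = 200,
) -> pd.DataFrame:
    """Build the unified CRE catalogue.

    Per state, the ``top_n`` peaks by score are kept; the pooled summits are
    then merged transitively wherever their ``merge_radius``-wide windows
    overlap (summits closer than ``merge_radius``). The merged summit is the
    rounded mean of member summits and the contributing states are recorded.

    Returns a DataFrame ``(cre, chrom, summit, source_states)`` sorted by
    (chrom, summit, cre); ids are assigned in that order.
    """
    pooled: list[tuple[str, int, str]] = []
    for state in sorted(peaks_by_state):
        peaks = peaks_by_state[state]
        if len(peaks) < top_n:
            if len(peaks) == 0:
                logger.warning("state %s contributed no peaks", state)
            top = list(peaks)
        else:
            order = sorted(
                range(len(peaks)),
                key=lambda i: (-peaks[i].score, peaks[i].interval.chrom, peaks[i].interval.start),
            )
            top = [peaks[i] for i in order[:top_n]]
        pooled.extend((p.interval.chrom, p.summit, state) for p in top)
    if not pooled:
        logger.warning("empty peak input: returning empty catalogue")
        return pd.DataFrame(columns=["cre", "chrom", "summit", "source_states"])

    pooled.sort()
    rows = []
    members: list[tuple[str, int, str]] = []

    def _flush() -> None:
        if not members:
            return
        mean = sum(m[1] for m in members) / len(members)
        summit = int(np.floor(mean + 0.5))
        states = ",".join(sorted({m[2] for m in members}))
        rows.append((members[0][0], summit, states))

    for chrom, summit, state in pooled:
        if members and (chrom != members[0][0] or summit - members[-1][1] >= merge_radius):
            _flush()
            members = []
        members.append((chrom, summit, state))
    _flush()

    cat = pd.DataFrame(rows, columns=["chrom", "summit", "source_states"])
    cat = cat.sort_values(["chrom", "summit"], kind="stable").reset_index(drop=True)
    cat.insert(0, "cre", [f"CRE{i:06d}" for i in range(len(cat))])
    return cat


def quantify_windows(
    catalogue: pd.DataFrame,
    fragments_by_sample: dict[str, pd.DataFrame],
    window: int,
) -> pd.DataFrame:
    """Count fragments overlapping the window around each CRE summit.

    The window is ``[summit - window//2, summit - window//2 + window)``;
    overlap means any shared base (half-open). Fragments on chromosomes absent
    from the catalogue are skipped with a counted warning.

    Returns an integer DataFrame indexed by CRE id, one column per sample.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    half = window // 2
    out = pd.DataFrame(
        0, index=pd.Index(catalogue["cre"], name="cre"), columns=sorted(fragments_by_sample)
    )
    known_chroms = set(catalogue["chrom"])
    for sample in sorted(fragments_by_sample):
        frags = fragments_by_sample[sample]
        n_skipped = int((~frags["chrom"].isin(known_chroms)).sum()) if len(frags) else 0
        if n_skipped:
            logger.warning(
                "sample %s: %d fragments on chromosomes absent from catalogue; skipped",
                sample,
                n_skipped,
            )
        for chrom, cat_c in catalogue.groupby("chrom", sort=False):
            fc = frags[frags["chrom"] == chrom]
            win_start = cat_c["summit"].to_numpy() - half
            win_end = win_start + window
            if fc.empty:
                continue
            starts = np.sort(fc["start"].to_numpy())
            ends = np.sort(fc["end"].to_numpy())
            # overlap count = #{start < win_end} - #{end <= win_start}
            n = np.searchsorted(starts, win_end, side="left") - np.searchsorted(
                ends, win_start, side="right"
            )
            out.loc[cat_c["cre"].to_numpy(), sample] = n
    return out


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Rank-based quantile normalization across columns.

    Each column's value at rank r is replaced by the mean over columns of the
    rank-r values; ties receive the mean of the reference values at their
    occupied rank positions.
    """
    arr = values.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = ref
        # average reference values within tie groups
        ser = pd.Series(assigned)
        out[:, j] = ser.groupby(pd.Series(col)).transform("mean").to_numpy()
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize_signal(matrix: pd.DataFrame, method: str = "log_quantile") -> pd.DataFrame:
    """Normalize a raw signal matrix.

    ``log_quantile`` (default): log10(count + 1) followed by quantile
    normalization across columns. ``log``: log transform only. ``quantile``:
    quantile normalization of the raw values. Single-column matrices fall back
    to the log transform with a warning.
    """
    if method not in ("log_quantile", "log", "quantile"):
        raise ValueError(f"unknown normalization method {method!r}")
    work = matrix.astype(float)
    if "log" in method:
        work = np.log10(work + 1.0)
    if "quantile" in method:
        if matrix.shape[1] < 2:
            logger.warning("single-column matrix: quantile step skipped")
            if method == "quantile":
                return work
        else:
            work = quantile_normalize(work)
    return work


def differential_count_test(
    matrix: pd.DataFrame,
    states: list[str] | np.ndarray,
    state_a: str = "A",
    state_b: str = "B",
    padj_threshold: float = 0.05,
    mark: str | None = None,
) -> pd.DataFrame:
    """NB Wald differential test of raw counts between two states.

    log2FC is ``state_a`` over ``state_b``. Rows with padj below
    ``padj_threshold`` are classed ``{state_a}-high`` / ``{state_b}-high`` by
    the sign of log2FC, all others ``nonvariable``.
    """
    states = np.asarray(states)
    sub = np.isin(states, [state_a, state_b])
    res = nb_wald_two_group(matrix.loc[:, sub], states[sub], ref_level=state_b)
    cls = np.where(
        (res["padj"] < padj_threshold) & (res["log2fc"] > 0),
        f"{state_a}-high",
        np.where(
            (res["padj"] < padj_threshold) & (res["log2fc"] < 0),
            f"{state_b}-high",
            "nonvariable",
        ),
    )
    out = pd.DataFrame(
        {
            "cre": matrix.index,
            "mark": mark if mark is not None else "",
            "log2fc": res["log2fc"].to_numpy(),
            "p": res["p"].to_numpy(),
            "padj": res["padj"].to_numpy(),
            "class": cls,
        }
    ).reset_index(drop=True)
    return out


def two_class_threshold(values: np.ndarray, n_candidates: int = 256) -> float:
    """Variance-minimizing two-class split of a pooled 1-D distribution.

    Scans candidate thresholds over the value range and returns the one
    minimizing the within-class variance sum (Otsu's criterion on raw values).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return 0.0
    lo, hi = v.min(), v.max()
    if lo == hi:
        return lo
    candidates = np.linspace(lo, hi, n_candidates + 2)[1:-1]
    best_t, best_score = candidates[0], np.inf
    for t in candidates:
        lower = v[v < t]
        upper = v[v >= t]
        if lower.size == 0 or upper.size == 0:
            continue
        score = lower.size * lower.var() + upper.size * upper.var()
        if score < best_score:
            best_score, best_t = score, t
    return float(best_t)


def threshold_variance_select(
    matrix: pd.DataFrame,
    states: list[str] | np.ndarray,
    state_a: str = "A",
    state_b: str = "B",
    quantile: float = 0.75,
    activity_cutoff: float | None = None,
    p_threshold: float = 0.05,
    mark: str | None = None,
) -> pd.DataFrame:
    """Two-step selection of variable CREs for threshold-based marks.

    Step 1 discards CREs whose maximum normalized signal is below the activity
    cutoff (default: two-class variance-minimizing split of the pooled
    distribution). Step 2 selects, among retained CREs, those whose
    between-state |mean difference| exceeds the ``quantile``-th quantile of
    differences AND whose two-sided rank-sum p is below ``p_threshold``.

    No multiplicity adjustment is applied on this path (the reported padj
    equals p): the rule is a raw-p screening rule, not a testing procedure.
    The reported log2fc converts the normalized (log10-scale) mean difference
    to the log2 scale.
    """
    states = np.asarray(states)
    idx_a = np.flatnonzero(states == state_a)
    idx_b = np.flatnonzero(states == state_b)
    arr = matrix.to_numpy(dtype=float)

    if activity_cutoff is None:
        activity_cutoff = two_class_threshold(arr[:, np.concatenate([idx_a, idx_b])].ravel())
    retained = arr.max(axis=1) >= activity_cutoff
    if not retained.any():
        logger.warning("all CREs below activity cutoff %.4g: empty selection", activity_cutoff)

    diff_log10 = arr[:, idx_a].mean(axis=1) - arr[:, idx_b].mean(axis=1)
    lfc = diff_log10 / _LOG10_2

    p = np.ones(arr.shape[0])
    ret_idx = np.flatnonzero(retained)
    for i in ret_idx:
        a, b = arr[i, idx_a], arr[i, idx_b]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            continue
        p[i] = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    abs_diff = np.abs(diff_log10)
    if ret_idx.size:
        diff_cut = np.quantile(abs_diff[ret_idx], quantile)
    else:
        diff_cut = np.inf
    selected = retained & (abs_diff > diff_cut) & (p < p_threshold)
    cls = np.where(
        selected & (diff_log10 > 0),
        f"{state_a}-high",
        np.where(selected & (diff_log10 < 0), f"{state_b}-high", "nonvariable"),
    )
    return pd.DataFrame(
        {
            "cre": matrix.index,
            "mark": mark if mark is not None else "",
            "log2fc": lfc,
            "p": p,
            "padj": p,
            "class": cls,
        }
    ).reset_index(drop=True)


def differential_fraction_percent(n_differential: int, n_total: int) -> float:
    """Percentage of the catalogue that is differential, to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_differential <= n_total):
        raise ValueError("n_differential must lie in [0, n_total]")
    return round(100.0 * n_differential / n_total, 1)


def summarize_differential(tables: list[pd.DataFrame], n_total: int) -> dict:
    """Union-over-marks differential summary.

    The differential CRE set is the union, across all per-mark tables, of
    CREs classed other than ``nonvariable``; the percentage is relative to the
    catalogue size.
    """
    union: set = set()
    per_mark = {}
    for tab in tables:
        diff = tab.loc[tab["class"] != "nonvariable", "cre"]
        mark = str(tab["mark"].iloc[0]) if len(tab) else ""
        per_mark[mark] = int(diff.size)
        union.update(diff)
    n_diff = len(union)
    return {
        "n_total": int(n_total),
        "n_differential": n_diff,
        "percent_differential": differential_fraction_percent(n_diff, n_total),
        "per_mark": per_mark,
    }
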