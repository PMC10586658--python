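"""CRE-to-gene association.

Two linking modes: promoter links (each CRE to its closest TSS within a
cutoff) and enhancer aggregation (per gene, the distance-weighted sum of the
signal of all CREs whose summit lies within a window of the TSS, promoter
CREs included at full weight).

The decay is a logistic curve in summit-to-TSS distance: full weight inside
the promoter radius, half weight at ``half_weight_distance_bp``, zero beyond
the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class WeightFunction:
    """Monotone non-increasing distance weight with w(d) in [0, 1].

    ``w(d) = 1`` for ``d <= full_weight_radius_bp``;
    ``w(d) = 2 exp(-mu x) / (1 + exp(-mu x))`` with ``x = d - full_weight_radius_bp``
    for distances up to ``max_distance_bp``; ``w(d) = 0`` beyond. ``mu`` is
    fixed by the half-weight condition ``w(half_weight_distance_bp) = 1/2``,
    which gives ``mu = ln(3) / (half_weight_distance_bp - full_weight_radius_bp)``.
    """

    full_weight_radius_bp: int = 2_000
    half_weight_distance_bp: int = 50_000
    max_distance_bp: int = 100_000

    def __post_init__(self) -> None:
        if not (0 <= self.full_weight_radius_bp < self.half_weight_distance_bp):
            raise ValueError("need 0 <= full_weight_radius < half_weight_distance")
        if self.half_weight_distance_bp > self.max_distance_bp:
            raise ValueError("half_weight_distance must not exceed max_distance")

    @property
    def mu(self) -> float:
        # solves 2 e^{-mu x} / (1 + e^{-mu x}) = 1/2  =>  e^{-mu x} = 1/3
        return np.log(3.0) / (self.half_weight_distance_bp - self.full_weight_radius_bp)

    def __call__(self, d) -> np.ndarray | float:
        return distance_weight(d, self)


def distance_weight(d, wf: WeightFunction):
    """Evaluate the weight at distance(s) ``d`` (bp, >= 0). Vectorized."""
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distance must be >= 0")
    x = np.maximum(d_arr - wf.full_weight_radius_bp, 0.0)
    e = np.exp(-wf.mu * x)
    w = 2.0 * e / (1.0 + e)
    w = np.where(d_arr <= wf.full_weight_radius_bp, 1.0, w)
    w = np.where(d_arr > wf.max_distance_bp, 0.0, w)
    if np.isscalar(d) or np.ndim(d) == 0:
        return float(w)
    return w


def link_closest_tss(
    catalogue: pd.DataFrame, genes: pd.DataFrame, max_bp: int = 20_000
) -> pd.DataFrame:
    """Link each CRE to its nearest TSS within ``max_bp`` (promoter links).

    Parameters
    ----------
    catalogue : DataFrame with columns ``cre, chrom, summit``.
    genes : DataFrame with columns ``gene, chrom, tss``.
    max_bp : maximum |TSS - summit| for a link.

    Returns
    -------
    DataFrame ``(cre, gene, distance)`` where distance is signed
    ``TSS - summit``; ties in |distance| break to the lexicographically
    smaller gene id. CREs without a TSS in range are absent.
    """
    rows = []
    for chrom, genes_c in genes.groupby("chrom", sort=False):
        cres_c = catalogue[catalogue["chrom"] == chrom]
        if cres_c.empty:
            continue
        # columns ordered by gene id: argmin returns the first (= smallest id)
        # among equidistant ties
        gsort = genes_c.sort_values("gene", kind="stable")
        tss = gsort["tss"].to_numpy(dtype=np.int64)
        gid = gsort["gene"].to_numpy()
        summits = cres_c["summit"].to_numpy(dtype=np.int64)
        cre_ids = cres_c["cre"].to_numpy()
        for lo in range(0, len(summits), 2048):
            block = summits[lo : lo + 2048]
            d = np.abs(tss[None, :] - block[:, None])
            j = np.argmin(d, axis=1)
            dist = d[np.arange(len(block)), j]
            keep = dist <= max_bp
            for cre_id, summit, jj in zip(cre_ids[lo : lo + 2048][keep], block[keep], j[keep]):
                rows.append((cre_id, gid[jj], int(tss[jj]) - int(summit)))
    out = pd.DataFrame(rows, columns=["cre", "gene", "distance"])
    return out.sort_values(["cre", "gene"], kind="stable").reset_index(drop=True)


def _pairs_within_window(
    catalogue: pd.DataFrame, genes: pd.DataFrame, max_bp: int
) -> pd.DataFrame:
    """All (gene, CRE) pairs with |TSS - summit| <= max_bp, via sorted search."""
    rows = []
    for chrom, cres_c in catalogue.groupby("chrom", sort=False):
        genes_c = genes[genes["chrom"] == chrom]
        if genes_c.empty:
            continue
        csort = cres_c.sort_values("summit", kind="stable")
        summits = csort["summit"].to_numpy()
        cre_ids = csort["cre"].to_numpy()
        for gene, tss in zip(genes_c["gene"], genes_c["tss"]):
            lo = np.searchsorted(summits, tss - max_bp, side="left")
            hi = np.searchsorted(summits, tss + max_bp, side="right")
            for k in range(lo, hi):
                rows.append((gene, cre_ids[k], abs(int(tss) - int(summits[k]))))
    return pd.DataFrame(rows, columns=["gene", "cre", "abs_distance"])


def aggregate_enhancer_signal(
    catalogue: pd.DataFrame,
    signal: pd.DataFrame,
    genes: pd.DataFrame,
    wf: WeightFunction,
) -> pd.DataFrame:
    """Distance-weighted sum of CRE signal per gene.

    For each gene and each sample column of ``signal`` (rows indexed by CRE
    id): ``sum over CREs with |TSS - summit| <= wf.max_distance_bp of
    w(|TSS - summit|) * signal``. Genes without a CRE in the window get 0.

    Returns a DataFrame indexed by gene id with the sample columns of
    ``signal`` plus ``n_cres`` (number of contributing CREs).
    """
    pairs = _pairs_within_window(catalogue, genes, wf.max_distance_bp)
    out = pd.DataFrame(
        0.0, index=pd.Index(genes["gene"], name="gene"), columns=list(signal.columns)
    )
    n_cres = pd.Series(0, index=out.index, name="n_cres")
    if not pairs.empty:
        pairs = pairs[pairs["cre"].isin(signal.index)]
    if not pairs.empty:
        w = distance_weight(pairs["abs_distance"].to_numpy(), wf)
        sig = signal.loc[pairs["cre"]].to_numpy()
        weighted = sig * w[:, None]
        contrib = pd.DataFrame(weighted, columns=signal.columns)
        contrib["gene"] = pairs["gene"].to_numpy()
        summed = contrib.groupby("gene").sum()
        out.loc[summed.index, :] = summed[signal.columns]
        counts = pairs.groupby("gene").size()
        n_cres.loc[counts.index] = counts
    out["n_cres"] = n_cres
    return out
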