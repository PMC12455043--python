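"""Decorrelated composite of multiple signals (DCMS) over the window grid.

Each window statistic is turned into a one-tailed rank-based empirical
p-value (the tail encoding "selection-like" signal: low pi, low Tajima's D,
high FST, high mean |iHS| and |xpEHH|), the p-value columns are combined as

    DCMS_j = sum_i w_i * ln((1 - p_ij) / p_ij),   w_i = 1 / sum_k |r_ik|,

with r the Pearson correlation matrix of the p-value columns, so that
redundant statistics are down-weighted rather than double counted.
Significance comes from a robust normal model of the DCMS distribution
(Huber M-location, MAD scale), Benjamini–Hochberg q-values, and windows
with q below the threshold are merged into outlier regions that are
"supported" when at least two significant windows overlap.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import ScanConfig

logger = logging.getLogger("polyscan")

__all__ = [
    "empirical_pvalues",
    "dcms_scores",
    "robust_tail_pvalues",
    "bh_qvalues",
    "storey_qvalues",
    "merge_outlier_regions",
    "composite_scan",
    "DEFAULT_TAILS",
]

#: tail per statistic encoding "selection-like" signal
DEFAULT_TAILS = {
    "pi": "lower",
    "tajima_d": "lower",
    "fst": "upper",
    "ihs": "upper",
    "xpehh": "upper",
}


def empirical_pvalues(values, tail: str = "upper") -> np.ndarray:
    """Rank-based one-tailed empirical probabilities p = r/(n+1).

    r counts values as or more extreme in the chosen tail; NaN values are
    excluded from ranking and returned as NaN.
    """
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    v = values[ok]
    if v.size < 2:
        raise ValueError("need >=2 non-null values for empirical p-values")
    out = np.full(values.shape, np.nan)
    if np.all(v == v[0]):
        logger.warning("statistic is constant; empirical p-values set to 0.5")
        out[ok] = 0.5
        return out
    order = np.sort(v)
    if tail == "upper":
        r = v.size - np.searchsorted(order, v, side="left")
    else:
        r = np.searchsorted(order, v, side="right")
    out[ok] = r / (v.size + 1.0)
    return out


def dcms_scores(p: pd.DataFrame, return_weights: bool = False):
    """DCMS per window from a matrix of per-statistic p-values.

    The correlation matrix is estimated over complete windows; a constant
    column gets zero off-diagonal correlation (weight 1) with a warning.
    Windows with missing statistics are scored from the available columns,
    rescaled by total weight / available weight so scores stay comparable.
    """
    if p.shape[1] < 1:
        raise ValueError("need at least one statistic column")
    arr = p.to_numpy(dtype=float)
    inside = (arr > 0) & (arr < 1)
    if np.any(~inside & ~np.isnan(arr)):
        raise ValueError("p-values must lie strictly in (0, 1)")
    complete = ~np.isnan(arr).any(axis=1)
    k = arr.shape[1]
    if k == 1:
        r = np.ones((1, 1))
    else:
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(arr[complete], rowvar=False)
        bad = np.isnan(r)
        if bad.any():
            logger.warning("constant p-value column; correlations set to 0")
            r[bad] = 0.0
        np.fill_diagonal(r, 1.0)
    w = 1.0 / np.abs(r).sum(axis=1)
    terms = w * np.log((1.0 - arr) / arr)
    avail = ~np.isnan(arr)
    n_partial = int((~complete & avail.any(axis=1)).sum())
    if n_partial:
        logger.info("%d windows scored from partial statistics (renormalised)", n_partial)
    w_avail = (avail * w).sum(axis=1)
    total_w = w.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        dcms = np.nansum(terms, axis=1) * (total_w / w_avail)
    dcms[w_avail == 0] = np.nan
    if return_weights:
        return dcms, w, r
    return dcms


def robust_tail_pvalues(dcms) -> np.ndarray:
    """Upper-tail normal probabilities under a robust location/scale fit.

    Location is the Huber M-estimate (tuning constant 1.345) of an
    intercept-only linear model; scale is 1.4826 * MAD of the residuals.
    """
    dcms = np.asarray(dcms, dtype=float)
    ok = ~np.isnan(dcms)
    x = dcms[ok]
    if x.size < 30:
        raise ValueError("need >=30 windows for the robust normal model")
    fit = sm.RLM(x, np.ones((x.size, 1)), M=sm.robust.norms.HuberT(t=1.345)).fit()
    location = float(fit.params[0])
    mad = float(np.median(np.abs(x - location)))
    if mad == 0:
        raise ValueError("degenerate score distribution (MAD = 0)")
    scale = 1.4826 * mad
    out = np.full(dcms.shape, np.nan)
    out[ok] = sps.norm.sf((x - location) / scale)
    return out


def bh_qvalues(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (NaN passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def storey_qvalues(p, lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values: BH scaled by the null-proportion estimate
    pi0 = #{p > lambda}/(n (1 - lambda)), clipped to (0, 1]."""
    p = np.asarray(p, dtype=float)
    ok = ~np.isnan(p)
    out = np.full(p.shape, np.nan)
    if ok.sum():
        pi0 = min(1.0, max((p[ok] > lambda_).mean() / (1 - lambda_), 1e-12))
        out[ok] = np.minimum(bh_qvalues(p[ok]) * pi0, 1.0)
    return out


def merge_outlier_regions(
    windows: pd.DataFrame,
    q: np.ndarray,
    q_max: float = 0.05,
    min_support: int = 2,
) -> pd.DataFrame:
    """Merge significant (q < q_max) overlapping/adjacent windows.

    Returns one row per region: chrom, start, end, support (member window
    count) and a ``supported`` flag (support >= min_support).  All regions
    are returned; callers select the supported subset for reporting.
    """
    q = np.asarray(q, dtype=float)
    sig = windows.loc[(q < q_max) & ~np.isnan(q), ["chrom", "start", "end"]]
    sig = sig.sort_values(["chrom", "start"])
    regions = []
    cur = None
    for chrom, start, end in sig.itertuples(index=False):
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur[2] = max(cur[2], end)
            cur[3] += 1
        else:
            if cur is not None:
                regions.append(tuple(cur))
            cur = [chrom, start, end, 1]
    if cur is not None:
        regions.append(tuple(cur))
    df = pd.DataFrame(regions, columns=["chrom", "start", "end", "support"])
    df["supported"] = df["support"] >= min_support
    return df


def composite_scan(
    window_stats: pd.DataFrame,
    config: ScanConfig | None = None,
    tails: dict[str, str] | None = None,
    qvalue_method: str = "bh",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full DCMS pass over a window-statistics table.

    Expects columns pi_A/pi_B, tajima_d, fst_hudson, mean_abs_ihs,
    mean_abs_xpehh; the within-population pi column is chosen by
    ``config.within_pop``.  Returns (dcms table, regions table).
    """
    config = config or ScanConfig()
    tails = tails or DEFAULT_TAILS
    pi_col = "pi_B" if config.within_pop == "popB" else "pi_A"
    stat_cols = {
        "pi": pi_col,
        "tajima_d": "tajima_d",
        "fst": "fst_hudson",
        "ihs": "mean_abs_ihs",
        "xpehh": "mean_abs_xpehh",
    }
    p = pd.DataFrame(index=window_stats.index)
    for stat, col in stat_cols.items():
        p[f"p_{stat}"] = empirical_pvalues(window_stats[col], tails[stat])
    dcms, w, r = dcms_scores(p, return_weights=True)
    table = window_stats[["chrom", "start", "end"]].copy()
    table = pd.concat([table, p], axis=1)
    table["dcms"] = dcms
    table["p_dcms"] = robust_tail_pvalues(dcms)
    qfun = storey_qvalues if qvalue_method == "storey" else bh_qvalues
    table["q"] = qfun(table["p_dcms"])
    regions = merge_outlier_regions(table, table["q"].to_numpy(),
                                    config.q_threshold, config.min_region_support)
    table.attrs["weights"] = dict(zip(stat_cols, w))
    table.attrs["correlation"] = r
    return table, regions
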