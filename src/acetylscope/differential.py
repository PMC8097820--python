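"""Housekeeping-anchored normalization, outlier screening and NB Wald tests.

The key analytical choice in a study where one group is globally
hyperacetylated is the normalization anchor: median-of-ratios style factors
assume most features are unchanged and therefore absorb a genome-wide shift
into the size factors, flattening it out of the estimates.  Anchoring the
factors on reads in saturated housekeeping-gene peaks — regions already full
of the mark, with little biological variance — preserves the global signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .nbglm import build_design_matrix, fit_nb_glm

LN2 = np.log(2.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def housekeeping_norm_factors(counts: pd.DataFrame, housekeeping_peak_ids) -> pd.Series:
    """Per-sample factors from housekeeping reads-in-peaks sums.

    factor_s = HK_RiP_s / geometric_mean(HK_RiP); the factors have geometric
    mean 1 and enter the NB model as log offsets.
    """
    hk_ids = [pid for pid in housekeeping_peak_ids if pid in counts.index]
    if not hk_ids:
        raise ValueError("no housekeeping peaks present in the count matrix")
    sums = counts.loc[hk_ids].sum(axis=0).astype(float)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(
            f"zero housekeeping counts in sample(s): {', '.join(zero.index)}"
        )
    log_sums = np.log(sums)
    return np.exp(log_sums - log_sums.mean()).rename("norm_factor")


def total_count_factors(counts: pd.DataFrame) -> pd.Series:
    """Total reads-in-peaks factors (geometric mean 1): CPM-style scaling."""
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    log_t = np.log(totals)
    return np.exp(log_t - log_t.mean()).rename("norm_factor")


def median_of_ratios_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq2-style size factors (median ratio to the geometric-mean sample),
    rescaled to geometric mean 1 for comparability with housekeeping factors."""
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_mat = np.log(mat)
    ok = np.isfinite(log_mat).all(axis=1)
    if ok.sum() < 1:
        raise ValueError("no feature with positive counts in all samples")
    ref = log_mat[ok].mean(axis=1)
    log_factors = np.median(log_mat[ok] - ref[:, None], axis=0)
    log_factors -= log_factors.mean()
    return pd.Series(np.exp(log_factors), index=counts.columns, name="norm_factor")


def select_housekeeping_peaks(peaks: pd.DataFrame, genes: pd.DataFrame,
                              min_coverage: float = 0.8) -> list:
    """Peaks saturating a housekeeping gene: overlap covers >= ``min_coverage``
    of the gene footprint (the gene span)."""
    hk = genes[genes["is_housekeeping"]]
    chosen = []
    for g in hk.itertuples():
        same = peaks[peaks["chrom"] == g.chrom]
        ov = np.minimum(same["end"], g.end) - np.maximum(same["start"], g.start)
        frac = ov.clip(lower=0) / (g.end - g.start)
        chosen.extend(same.loc[frac >= min_coverage, "peak_id"].tolist())
    return sorted(set(chosen))


def log2_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) over per-sample totals of the matrix itself."""
    totals = counts.sum(axis=0).astype(float)
    return np.log2(counts.div(totals, axis=1) * 1e6 + 1.0)


def detect_outliers(counts: pd.DataFrame, threshold_mads: float = 3.0,
                    min_mad: float = 1e-3) -> list:
    """Flag samples whose median Spearman correlation to the others is more
    than ``threshold_mads`` MADs below the across-sample median.

    The MAD is scaled by 1.4826 (the normal-consistent estimator of the
    standard deviation) and floored at ``min_mad`` so that near-identical
    sample sets (zero spread) flag nothing.
    """
    if counts.shape[1] < 4:
        raise ValueError("need at least 4 samples for outlier screening")
    lc = log2_cpm(counts).to_numpy()
    rho = spearmanr(lc).statistic
    rho = np.atleast_2d(rho)
    np.fill_diagonal(rho, np.nan)
    med = np.nanmedian(rho, axis=0)
    center = np.median(med)
    mad = max(1.4826 * np.median(np.abs(med - center)), min_mad)
    flagged = np.where(med < center - threshold_mads * mad)[0]
    return [counts.columns[i] for i in flagged]


def independent_filter(wald_p: np.ndarray, mean_count: np.ndarray,
                       alpha: float = 0.05, n_quantiles: int = 20):
    """Choose the mean-count filter threshold maximizing BH discoveries.

    Returns (adj_p, threshold): features below the threshold get NaN adjusted
    p and never count as discoveries; ties favour the weakest filter.
    """
    quantiles = np.linspace(0.0, 0.95, n_quantiles)
    best_adj, best_n, best_thr = None, -1, 0.0
    for q in quantiles:
        thr = np.quantile(mean_count, q)
        mask = (mean_count >= thr) & ~np.isnan(wald_p)
        if mask.sum() == 0:
            continue
        adj = np.full(wald_p.shape, np.nan)
        adj[mask] = bh_adjust(wald_p[mask])
        n_rej = int((adj[mask] < alpha).sum())
        if n_rej > best_n:
            best_adj, best_n, best_thr = adj, n_rej, thr
    return best_adj, best_thr


def nb_wald_test(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    norm_factors: pd.Series,
    design: list | None = None,
    alpha: float = 0.05,
    independent_filtering: bool = True,
    shrink_weight: float = 0.5,
) -> pd.DataFrame:
    """Covariate-adjusted per-peak NB Wald test of the case/control contrast.

    ``design`` lists metadata covariate columns beyond the group; control is
    the reference level, so log2fc > 0 means higher counts in cases.  Returns
    a table with log2fc, se, wald_p, adj_p (BH after optional independent
    filtering on the mean normalized count) and the DAR flag (adj_p < alpha).
    """
    meta = metadata.loc[counts.columns]
    X, names = build_design_matrix(meta, design or [])
    nf = norm_factors.loc[counts.columns].to_numpy(dtype=float)
    Y = counts.to_numpy(dtype=float)
    fit = fit_nb_glm(Y, X, offset=np.log(nf), design_columns=names,
                     shrink_weight=shrink_weight)
    group_col = names[1]
    wald_p, _ = fit.wald_test(group_col)
    wald_p = np.where(fit.converged, wald_p, np.nan)
    mean_count = (Y / nf).mean(axis=1)
    if independent_filtering:
        adj_p, _ = independent_filter(wald_p, mean_count, alpha=alpha)
    else:
        adj_p = bh_adjust(wald_p)
    j = names.index(group_col)
    out = pd.DataFrame(
        {
            "peak_id": counts.index,
            "mean_count": mean_count,
            "log2fc": fit.beta[:, j] / LN2,
            "se": fit.se[:, j] / LN2,
            "wald_p": wald_p,
            "adj_p": adj_p,
            "dispersion": fit.alpha,
            "converged": fit.converged,
        }
    ).set_index("peak_id")
    out["is_dar"] = out["adj_p"] < alpha
    return out


def ma_summary(results: pd.DataFrame) -> dict:
    """MA-style table (log10 mean, log2fc, DAR flag) + genome-wide median lfc."""
    table = pd.DataFrame(
        {
            "log10_mean": np.log10(results["mean_count"] + 1.0),
            "log2fc": results["log2fc"],
            "is_dar": results["is_dar"],
        },
        index=results.index,
    )
    return {"table": table, "median_log2fc": float(results["log2fc"].median())}
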