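"""Regulatory context of differential acetylation: acetyltransferase /
deacetylase binding-site balance and GC content.

If hyperacetylation is driven by loss of a deacetylation brake, it should be
strongest where the writer (a p300-like acetyltransferase) binds densely and
alternative erasers (non-SIRT1 HDAC-like deacetylases) bind sparsely.  These
statistics test that: per-peak binding-site counts from interval tracks, the
log site-count ratio contrasted between DAR and non-DAR peaks, and a linear
model of one-sided hyperacetylation evidence on the two counts.  GC content
of DARs is contrasted against a length-matched background.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from intervaltree import IntervalTree
from scipy.stats import ks_2samp, mannwhitneyu

from .genomic import gc_content

PSEUDOCOUNT = 0.01


def count_binding(peaks: pd.DataFrame, site_tracks: dict[str, pd.DataFrame],
                  activator: str = "activator") -> pd.DataFrame:
    """Per-peak number of overlapping (>=1 bp) sites per factor.

    All non-activator factors are summed into the deacetylase count.  Returns
    activator_sites, deacetylase_sites, the log ratio
    ln((act + 0.01) / (deac + 0.01)) and the excluded flag for peaks with no
    site of either kind.
    """
    counts = {}
    for factor, track in site_tracks.items():
        trees: dict[str, IntervalTree] = {}
        for row in track.itertuples():
            trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
        counts[factor] = np.array(
            [
                len(trees.get(p.chrom, IntervalTree()).overlap(p.start, p.end))
                for p in peaks.itertuples()
            ]
        )
    act = counts.get(activator, np.zeros(len(peaks), dtype=int))
    deac = sum(
        (v for k, v in counts.items() if k != activator),
        np.zeros(len(peaks), dtype=int),
    )
    out = pd.DataFrame(
        {
            "activator_sites": act,
            "deacetylase_sites": deac,
            "log_ratio": np.log((act + PSEUDOCOUNT) / (deac + PSEUDOCOUNT)),
            "excluded": (act == 0) & (deac == 0),
        },
        index=peaks["peak_id"].to_numpy(),
    )
    return out


def gene_level_binding(binding: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Sum per-peak site counts over each gene's annotated peaks."""
    ann = annotations.dropna(subset=["gene_id"])[["peak_id", "gene_id"]]
    ann = ann.drop_duplicates()
    merged = ann.join(
        binding[["activator_sites", "deacetylase_sites"]], on="peak_id"
    )
    agg = merged.groupby("gene_id")[["activator_sites", "deacetylase_sites"]].sum()
    agg["log_ratio"] = np.log(
        (agg["activator_sites"] + PSEUDOCOUNT)
        / (agg["deacetylase_sites"] + PSEUDOCOUNT)
    )
    agg["excluded"] = (agg["activator_sites"] == 0) & (agg["deacetylase_sites"] == 0)
    return agg


def binding_ratio_contrast(binding: pd.DataFrame, dar_flags: pd.Series,
                           scope: str = "all_genes") -> dict:
    """Contrast the binding log-ratio of hyperacetylated DAR vs non-DAR peaks.

    Two-sample two-sided Kolmogorov–Smirnov for the genome-wide scope, and a
    two-sided Wilcoxon rank-sum for the (smaller) implicated-gene scope.
    Excluded peaks (no sites at all) never enter.
    """
    usable = binding[~binding["excluded"]]
    flags = dar_flags.reindex(usable.index).fillna(False).astype(bool)
    x = usable.loc[flags, "log_ratio"].to_numpy()
    y = usable.loc[~flags, "log_ratio"].to_numpy()
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >=2 peaks in each class for the contrast")
    if scope == "all_genes":
        stat, p = ks_2samp(x, y, alternative="two-sided")
        test = "ks"
    elif scope == "implicated_only":
        res = mannwhitneyu(x, y, alternative="two-sided")
        stat, p = res.statistic, res.pvalue
        test = "rank_sum"
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return {
        "test": test,
        "statistic": float(stat),
        "p": float(p),
        "median_dar": float(np.median(x)),
        "median_non_dar": float(np.median(y)),
        "n_dar": len(x),
        "n_non_dar": len(y),
    }


def p_hyper(p, lfc):
    """One-sided hyperacetylation probability folded from a two-sided p:
    p/2 when lfc >= 0, 1 - p/2 when lfc < 0.  Vectorized."""
    p = np.asarray(p, dtype=float)
    lfc = np.asarray(lfc, dtype=float)
    out = np.where(lfc >= 0, p / 2.0, 1.0 - p / 2.0)
    return float(out) if out.ndim == 0 else out


def hyperacetylation_model(binding: pd.DataFrame, p_hyper_values: pd.Series,
                           implicated: pd.Series) -> pd.DataFrame:
    """OLS of -log10(p_hyper) on activator count + deacetylase count +
    implicated-gene flag, over peaks with at least one binding site."""
    usable = binding[~binding["excluded"]]
    y = -np.log10(
        np.clip(p_hyper_values.reindex(usable.index).to_numpy(float),
                np.finfo(float).tiny, 1.0)
    )
    X = pd.DataFrame(
        {
            "activator_sites": usable["activator_sites"].astype(float),
            "deacetylase_sites": usable["deacetylase_sites"].astype(float),
            "PDgene": implicated.reindex(usable.index).fillna(False).astype(float),
        },
        index=usable.index,
    )
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear design in hyperacetylation model")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return pd.DataFrame(
        {"coef": fit.params, "ci_low": ci[0], "ci_high": ci[1], "p": fit.pvalues}
    )


def _length_matched_draw(dar_lengths, bg_lengths, rng, tolerance: float = 0.1):
    """One background sample length-matched to the DAR set, nearest-length
    without replacement; the relative tolerance widens (with a warning) when
    a stratum runs dry."""
    order = rng.permutation(len(dar_lengths))
    available = np.ones(len(bg_lengths), dtype=bool)
    chosen = np.empty(len(dar_lengths), dtype=int)
    sort_idx = np.argsort(bg_lengths)
    sorted_len = bg_lengths[sort_idx]
    for i in order:
        target = dar_lengths[i]
        pos = np.searchsorted(sorted_len, target)
        best, best_d = -1, np.inf
        for j in range(max(0, pos - 50), min(len(sort_idx), pos + 50)):
            k = sort_idx[j]
            if not available[k]:
                continue
            d = abs(bg_lengths[k] - target)
            if d < best_d:
                best, best_d = k, d
        if best < 0 or best_d > tolerance * target:
            cand = np.where(available)[0]
            if len(cand) == 0:
                raise ValueError("background exhausted during length matching")
            if best < 0:
                best = cand[np.argmin(np.abs(bg_lengths[cand] - target))]
            warnings.warn("length-matching tolerance widened for a stratum")
        available[best] = False
        chosen[i] = best
    return chosen


def gc_contrast(dar_peaks: pd.DataFrame, background_peaks: pd.DataFrame,
                sequences: dict, n_draws: int = 10, seed: int = 0) -> dict:
    """Mean GC of DARs vs a length-matched background, with a rank-sum test.

    Repeats the background draw ``n_draws`` times and reports the median mean
    GC difference and median p alongside the per-draw values.
    """
    rng = np.random.default_rng(seed)
    dar_gc = np.array([gc_content(sequences[p]) for p in dar_peaks["peak_id"]])
    bg_ids = background_peaks["peak_id"].to_numpy()
    bg_gc = np.array([gc_content(sequences[p]) for p in bg_ids])
    dar_len = (dar_peaks["end"] - dar_peaks["start"]).to_numpy(float)
    bg_len = (background_peaks["end"] - background_peaks["start"]).to_numpy(float)
    diffs, ps, matched_idx = [], [], []
    for _ in range(n_draws):
        idx = _length_matched_draw(dar_len, bg_len, rng)
        matched = bg_gc[idx]
        diffs.append(float(np.nanmean(dar_gc) - np.nanmean(matched)))
        ps.append(float(mannwhitneyu(
            dar_gc[~np.isnan(dar_gc)], matched[~np.isnan(matched)],
            alternative="two-sided",
        ).pvalue))
        matched_idx.append(idx)
    return {
        "mean_gc_dar": float(np.nanmean(dar_gc)),
        "median_gc_difference": float(np.median(diffs)),
        "median_p": float(np.median(ps)),
        "per_draw_differences": diffs,
        "per_draw_p": ps,
        "matched_lengths_example": bg_len[matched_idx[0]],
        "dar_lengths": dar_len,
    }
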