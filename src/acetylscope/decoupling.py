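"""Promoter-mark / expression coupling, its group contrast and gene-set
scoring.

Active-promoter acetylation normally tracks transcription across
individuals; a disease state can attenuate that coupling genome-wide.  The
pipeline: (1) remove nuisance covariates from both count matrices while
preserving the group effect, via refitting the NB model with covariates at
reference/mean values; (2) per gene and group, Pearson-correlate the
adjusted promoter acetylation with the adjusted expression, keeping the best
promoter per group when several exist; (3) compare the two groups'
correlation distributions across an absolute-correlation threshold sweep;
(4) score user-supplied gene sets against resampled null mean scores
(gene-score resampling, low score = more decoupled = hit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .nbglm import build_design_matrix, fit_nb_glm


@dataclass
class AdjustedCounts:
    matrix: pd.DataFrame       # feature x sample, covariate-adjusted scale
    covariates_removed: list
    group_preserved: bool = True


def adjust_counts(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates: list,
    norm_factors: pd.Series | None = None,
) -> AdjustedCounts:
    """Counts with covariate effects removed, group effect preserved.

    Fits the NB log-linear model (group + covariates, log norm-factor
    offset), then maps each observation through the coefficient-based
    correction ``y * exp((x_adj - x)'beta - log nf)`` where ``x_adj`` sets
    categorical covariates to the reference level and continuous covariates
    to their mean — i.e. predicted-plus-residual on the log scale.  With no
    covariates this reduces exactly to ``y / nf`` (normalized counts).
    """
    meta = metadata.loc[counts.columns]
    for cov in covariates:
        if cov not in meta.columns:
            raise ValueError(f"covariate {cov!r} absent from metadata")
    if norm_factors is None:
        nf = np.ones(counts.shape[1])
    else:
        nf = norm_factors.loc[counts.columns].to_numpy(float)
    if not covariates:
        # nothing to remove: adjusted counts are exactly normalized counts
        return AdjustedCounts(matrix=counts / nf, covariates_removed=[])
    X, names = build_design_matrix(meta, covariates)
    fit = fit_nb_glm(counts.to_numpy(float), X, offset=np.log(nf),
                     design_columns=names)
    X_adj = X.copy()
    X_adj[:, 2:] = 0.0  # dummy columns to reference, centered continuous to mean
    # log-scale correction, clipped so degenerate fits (all-zero features)
    # cannot overflow the exp
    delta = np.clip((X_adj - X) @ fit.beta.T, -30.0, 30.0)  # (samples, features)
    adjusted = counts.to_numpy(float) * np.exp(delta.T) / nf[None, :]
    return AdjustedCounts(
        matrix=pd.DataFrame(adjusted, index=counts.index, columns=counts.columns),
        covariates_removed=list(covariates),
    )


def promoter_expression_correlation(
    adjusted_chip: pd.DataFrame,
    adjusted_rna: pd.DataFrame,
    promoter_annotations: pd.DataFrame,
    group_labels: pd.Series,
    peak_order: pd.Series | None = None,
    use_absolute: bool = False,
    log2_scale: bool = True,
) -> pd.DataFrame:
    """Per-gene, per-group Pearson r between promoter acetylation and
    expression, reduced over promoters by the maximum (signed by default).

    ``promoter_annotations`` maps peak_id -> gene_id (promoter-category
    records).  Groups are correlated independently, each choosing its own
    best promoter; ties break by genomic order when ``peak_order`` (e.g. the
    peak start coordinate) is given, else by peak id.  Zero-variance vectors
    give a missing correlation.  By default both matrices are taken to
    log2(x + 1) before correlating, the scale on which NB log-linear signal
    is additive; pass ``log2_scale=False`` to correlate the adjusted counts
    directly.
    """
    samples = adjusted_chip.columns.intersection(adjusted_rna.columns)
    if log2_scale:
        adjusted_chip = np.log2(adjusted_chip + 1.0)
        adjusted_rna = np.log2(adjusted_rna + 1.0)
    groups = group_labels.loc[samples]
    ann = promoter_annotations.dropna(subset=["gene_id"])
    ann = ann[ann["peak_id"].isin(adjusted_chip.index)]
    order = (
        peak_order.reindex(ann["peak_id"].unique())
        if peak_order is not None
        else pd.Series(ann["peak_id"].unique(), index=ann["peak_id"].unique())
    )
    rows = []
    for gene_id, sub in ann.groupby("gene_id"):
        if gene_id not in adjusted_rna.index:
            continue
        peak_ids = sorted(set(sub["peak_id"]), key=lambda p: (order.loc[p], p))
        rec = {"gene_id": gene_id}
        for label, key in (("control", "r_control"), ("case", "r_case")):
            m = (groups == label).to_numpy()
            if m.sum() < 3:
                raise ValueError(f"group {label!r} has fewer than 3 samples")
            y = adjusted_rna.loc[gene_id, samples].to_numpy(float)[m]
            best_r, best_peak = None, None
            for pid in peak_ids:
                x = adjusted_chip.loc[pid, samples].to_numpy(float)[m]
                if np.std(x) == 0 or np.std(y) == 0:
                    continue
                r = float(np.corrcoef(x, y)[0, 1])
                score = abs(r) if use_absolute else r
                if best_r is None or score > (abs(best_r) if use_absolute else best_r):
                    best_r, best_peak = r, pid
            rec[key] = best_r if best_r is not None else np.nan
            rec[f"peak_{label}"] = best_peak
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("gene_id").sort_index()
    out["delta"] = out["r_case"] - out["r_control"]
    return out


def hodges_lehmann_shift(x: np.ndarray, y: np.ndarray) -> float:
    """Hodges–Lehmann estimate of the location shift x - y (median of all
    pairwise differences)."""
    return float(np.median(x[:, None] - y[None, :]))


def threshold_sweep(correlations: pd.DataFrame, thresholds) -> pd.DataFrame:
    """Group contrast of coupling across absolute-correlation thresholds.

    For each threshold t, keeps genes with |r| > t in at least one group and
    compares r_control vs r_case by two-sided Wilcoxon rank-sum; reports
    group medians, the Hodges–Lehmann shift (case - control), n genes kept
    and a stability flag (n < 10 is flagged unstable).
    """
    rows = []
    df = correlations.dropna(subset=["r_control", "r_case"])
    for t in thresholds:
        kept = df[(df["r_control"].abs() > t) | (df["r_case"].abs() > t)]
        row = {"threshold": t, "n_genes": len(kept)}
        if len(kept) < 2:
            row.update(
                {"median_control": np.nan, "median_case": np.nan,
                 "shift": np.nan, "p": np.nan, "unstable": True}
            )
            rows.append(row)
            continue
        if len(kept) < 10:
            warnings.warn(f"threshold {t}: only {len(kept)} genes retained")
        x = kept["r_case"].to_numpy()
        y = kept["r_control"].to_numpy()
        res = mannwhitneyu(x, y, alternative="two-sided")
        row.update(
            {
                "median_control": float(np.median(y)),
                "median_case": float(np.median(x)),
                "shift": hodges_lehmann_shift(x, y),
                "p": float(res.pvalue),
                "unstable": len(kept) < 10,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def gene_score_resampling(
    scores: pd.Series,
    gene_set,
    n_resamples: int = 10_000,
    seed: int = 0,
    direction: str = "low_is_hit",
) -> dict:
    """Empirical gene-set p by resampling same-size random sets.

    Observed statistic = mean score of the set; the null distribution is the
    mean of ``n_resamples`` random same-size gene sets drawn from the scored
    universe.  Under ``low_is_hit`` (e.g. ΔCor scores where lower = more
    decoupled), p = (1 + #{null <= observed}) / (n_resamples + 1).
    """
    if direction not in {"low_is_hit", "high_is_hit"}:
        raise ValueError(f"unknown direction {direction!r}")
    scores = scores.dropna()
    gene_set = [g for g in gene_set if g in scores.index]
    k = len(gene_set)
    if k == 0 or k >= len(scores):
        raise ValueError("gene set must be a non-empty proper subset of the universe")
    rng = np.random.default_rng(seed)
    observed = float(scores.loc[gene_set].mean())
    values = scores.to_numpy()
    null = np.empty(n_resamples)
    for i in range(n_resamples):
        null[i] = values[rng.choice(len(values), size=k, replace=False)].mean()
    if direction == "low_is_hit":
        p = (1.0 + np.sum(null <= observed)) / (n_resamples + 1.0)
    else:
        p = (1.0 + np.sum(null >= observed)) / (n_resamples + 1.0)
    return {
        "observed_mean": observed,
        "p": float(p),
        "n_resamples": n_resamples,
        "set_size": k,
    }
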