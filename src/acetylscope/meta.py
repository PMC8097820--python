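"""Two-cohort harmonization, Fisher meta-analysis and replication statistics.

Cohorts called peaks independently, so their peak-sets do not align
coordinate-by-coordinate.  Harmonization pairs peaks through their biology
instead: for every (gene, structural category) key present in both cohorts,
one peak per cohort is paired (common peak pair), with multiplicity resolved
by minimum total midpoint distance.  Evidence across cohorts is combined by
Fisher's method (chi-square with 4 df on two p-values), and replication is
quantified by hypergeometric overlap tests at the gene and pair level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import linear_sum_assignment
from scipy.stats import chi2, hypergeom

from .differential import bh_adjust

_TINY = np.finfo(float).tiny


def fisher_meta(p_a, p_b):
    """Fisher-combined p-value: X^2 = -2(ln pA + ln pB) ~ chi2(4 df).

    Zero p-values are clamped to the smallest positive float.  Accepts
    scalars or arrays.
    """
    p_a = np.clip(np.asarray(p_a, dtype=float), _TINY, 1.0)
    p_b = np.clip(np.asarray(p_b, dtype=float), _TINY, 1.0)
    x2 = -2.0 * (np.log(p_a) + np.log(p_b))
    out = chi2.sf(x2, df=4)
    return float(out) if out.ndim == 0 else out


def _midpoints(results_peaks: pd.DataFrame) -> pd.Series:
    return (results_peaks["start"] + results_peaks["end"]) / 2.0


def harmonize(
    annotations_a: pd.DataFrame,
    annotations_b: pd.DataFrame,
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    peaks_a: pd.DataFrame,
    peaks_b: pd.DataFrame,
) -> pd.DataFrame:
    """Pair peaks across cohorts by shared (gene, category) annotation.

    When several peaks share a key in either cohort, the one-to-one pairing
    minimizing the total midpoint distance is used (optimal assignment);
    leftover candidates stay unpaired and each peak joins at most one pair
    per key.  Returns the CommonPeakPair table with both cohorts' statistics,
    the Fisher metaP, its BH adjustment and the concordance flag.
    """
    mid_a = _midpoints(peaks_a.set_index("peak_id"))
    mid_b = _midpoints(peaks_b.set_index("peak_id"))

    def _usable(ann, results):
        df = ann.dropna(subset=["gene_id"])
        df = df[df["category"] != "intergenic"]
        return df[df["peak_id"].isin(results.index)]

    ann_a = _usable(annotations_a, results_a)
    ann_b = _usable(annotations_b, results_b)
    keys_a = ann_a.groupby(["gene_id", "category"])["peak_id"].agg(
        lambda s: sorted(set(s))
    )
    keys_b = ann_b.groupby(["gene_id", "category"])["peak_id"].agg(
        lambda s: sorted(set(s))
    )
    rows = []
    for key in keys_a.index.intersection(keys_b.index):
        cand_a, cand_b = keys_a.loc[key], keys_b.loc[key]
        cost = np.abs(
            mid_a.loc[cand_a].to_numpy()[:, None]
            - mid_b.loc[cand_b].to_numpy()[None, :]
        )
        ia, ib = linear_sum_assignment(cost)
        for i, j in zip(ia, ib):
            pa, pb = cand_a[i], cand_b[j]
            rows.append(
                (
                    key[0], key[1], pa, pb,
                    results_a.loc[pa, "wald_p"], results_b.loc[pb, "wald_p"],
                    results_a.loc[pa, "log2fc"], results_b.loc[pb, "log2fc"],
                )
            )
    pairs = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "category", "peak_id_A", "peak_id_B",
            "p_A", "p_B", "lfc_A", "lfc_B",
        ],
    )
    if len(pairs):
        pairs["meta_p"] = fisher_meta(pairs["p_A"], pairs["p_B"])
        pairs["adj_meta_p"] = bh_adjust(pairs["meta_p"])
        pairs["concordant"] = np.sign(pairs["lfc_A"]) == np.sign(pairs["lfc_B"])
    else:
        for c in ("meta_p", "adj_meta_p"):
            pairs[c] = pd.Series(dtype=float)
        pairs["concordant"] = pd.Series(dtype=bool)
    return pairs.sort_values(
        ["gene_id", "category", "peak_id_A"]
    ).reset_index(drop=True)


def hypergeom_overlap(n_universe: int, n_set_a: int, n_set_b: int,
                      n_overlap: int) -> float:
    """Upper-tail hypergeometric p for an overlap of two sets in a universe."""
    if n_set_a > n_universe or n_set_b > n_universe:
        raise ValueError("set larger than its universe")
    if n_overlap > min(n_set_a, n_set_b):
        raise ValueError("overlap larger than the smaller set")
    return float(hypergeom.sf(n_overlap - 1, n_universe, n_set_a, n_set_b))


def replication_summary(
    pairs: pd.DataFrame,
    dar_genes_a: set,
    dar_genes_b: set,
    dar_peaks_a: set,
    dar_peaks_b: set,
    gene_universe: set,
) -> dict:
    """Two-level replication: genes DAR-bearing in both cohorts, and pairs
    that are DARs in both cohorts, each with a hypergeometric overlap test
    against its explicitly supplied universe.
    """
    if max(len(dar_genes_a), len(dar_genes_b)) > len(gene_universe):
        raise ValueError("gene universe smaller than its category counts")
    genes_a = dar_genes_a & gene_universe
    genes_b = dar_genes_b & gene_universe
    replicated_genes = genes_a & genes_b
    gene_p = hypergeom_overlap(
        len(gene_universe), len(genes_a), len(genes_b), len(replicated_genes)
    )
    pair_dar = pairs[
        pairs["peak_id_A"].isin(dar_peaks_a) & pairs["peak_id_B"].isin(dar_peaks_b)
    ]
    n_pairs = len(pairs)
    n_a = int(pairs["peak_id_A"].isin(dar_peaks_a).sum())
    n_b = int(pairs["peak_id_B"].isin(dar_peaks_b).sum())
    pair_p = hypergeom_overlap(n_pairs, n_a, n_b, len(pair_dar)) if n_pairs else 1.0
    return {
        "replicated_genes": sorted(replicated_genes),
        "n_replicated_genes": len(replicated_genes),
        "gene_universe_size": len(gene_universe),
        "gene_overlap_p": gene_p,
        "replicated_dars": pair_dar[["gene_id", "peak_id_A", "peak_id_B"]],
        "n_replicated_dars": len(pair_dar),
        "pair_universe_size": n_pairs,
        "pair_overlap_p": pair_p,
    }


def egl_model(gene_stats: pd.DataFrame, direction: str | None = None) -> pd.DataFrame:
    """OLS of -log10(p) on the implicated-gene flag, log10 effective gene
    length and the number of regions per gene.

    ``gene_stats`` has one row per (region, gene) with columns ``p`` (meta or
    cohort p), ``egl``, ``n_regions``, ``is_implicated`` and, when
    ``direction`` is requested, ``lfc_A``/``lfc_B`` used to subset to
    concordantly hyper- ('hyper') or hypoacetylated ('hypo') regions.
    Returns the coefficient table with 95% CIs.
    """
    df = gene_stats.copy()
    if direction == "hyper":
        df = df[(df["lfc_A"] > 0) & (df["lfc_B"] > 0)]
    elif direction == "hypo":
        df = df[(df["lfc_A"] < 0) & (df["lfc_B"] < 0)]
    elif direction is not None:
        raise ValueError(f"unknown direction {direction!r}")
    if (df["egl"] <= 0).any():
        raise ValueError("EGL must be positive")
    y = -np.log10(np.clip(df["p"].to_numpy(float), _TINY, 1.0))
    X = pd.DataFrame(
        {
            "PDgene": df["is_implicated"].astype(float),
            "log10_EGL": np.log10(df["egl"].astype(float)),
            "n_regions": df["n_regions"].astype(float),
        },
        index=df.index,
    )
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear design in EGL model")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return pd.DataFrame(
        {
            "coef": fit.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": fit.pvalues,
        }
    )
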