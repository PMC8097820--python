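"""Housekeeping normalization, outlier screening, the NB Wald test
(calibration, recovery, cross-check against an independent DESeq2
reimplementation) and BH adjustment against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from acetylscope import differential, simulate


def brute_force_bh(p):
    """Independent step-up oracle: adj_i = min over j>=i of m*p_(j)/j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj


# --------------------------------------------------------------- norm factors


def test_housekeeping_factor_worked_example():
    counts = pd.DataFrame({"s1": [150, 50], "s2": [300, 100]},
                          index=["hk1", "hk2"])
    f = differential.housekeeping_norm_factors(counts, ["hk1", "hk2"])
    assert f["s1"] == pytest.approx(0.70710678, abs=1e-6)
    assert f["s2"] == pytest.approx(1.41421356, abs=1e-6)
    assert np.exp(np.log(f).mean()) == pytest.approx(1.0)


def test_housekeeping_factor_identity_and_homogeneity():
    counts = pd.DataFrame(
        {f"s{i}": [100, 200] for i in range(4)}, index=["hk1", "hk2"]
    )
    f = differential.housekeeping_norm_factors(counts, ["hk1", "hk2"])
    np.testing.assert_allclose(f, 1.0)
    scaled = counts.copy()
    scaled["s2"] = scaled["s2"] * 5
    f2 = differential.housekeeping_norm_factors(scaled, ["hk1", "hk2"])
    # the scaled sample's factor rises 5x relative to every other sample
    np.testing.assert_allclose((f2["s2"] / f2["s0"]) / (f["s2"] / f["s0"]), 5.0)
    assert np.exp(np.log(f2).mean()) == pytest.approx(1.0)


def test_housekeeping_zero_counts_error_names_sample():
    counts = pd.DataFrame({"good": [10, 5], "empty": [0, 0]}, index=["hk1", "hk2"])
    with pytest.raises(ValueError, match="empty"):
        differential.housekeeping_norm_factors(counts, ["hk1", "hk2"])


def test_select_housekeeping_peaks_saturation_rule(small_study):
    coh = small_study.cohorts["A"]
    chosen = differential.select_housekeeping_peaks(coh.peaks, small_study.genes)
    assert set(chosen) == coh.truth.housekeeping_peaks


# ------------------------------------------------------------------ outliers


def test_outlier_screen_null_and_positive():
    cfg = simulate.SimulationConfig(n_peaks=1000, n_genes=300, seed=8)
    coh = simulate.generate_cohort(cfg, simulate.generate_gene_models(cfg))
    assert differential.detect_outliers(coh.counts) == []
    corrupted = coh.counts.copy()
    victim = corrupted.columns[2]
    corrupted[victim] = np.random.default_rng(1).permutation(
        corrupted[victim].to_numpy()
    )
    assert differential.detect_outliers(corrupted) == [victim]


def test_outlier_screen_degenerate_identical_samples():
    col = np.arange(1, 101)
    counts = pd.DataFrame({f"s{i}": col for i in range(4)})
    assert differential.detect_outliers(counts) == []


def test_outlier_screen_needs_four_samples():
    counts = pd.DataFrame({"a": [1, 2], "b": [2, 3], "c": [3, 4]})
    with pytest.raises(ValueError):
        differential.detect_outliers(counts)


# ----------------------------------------------------------------- NB Wald


def _null_cohort(seed):
    cfg = simulate.SimulationConfig(
        n_peaks=5000, n_genes=1200, shift_fraction=0.0, global_shift=1.0, seed=seed
    )
    return simulate.generate_cohort(cfg, simulate.generate_gene_models(cfg))


def test_identical_group_columns_give_zero_lfc():
    rng = np.random.default_rng(0)
    half = rng.poisson(100, size=(200, 5))
    counts = pd.DataFrame(
        np.hstack([half, half]),
        index=[f"p{i}" for i in range(200)],
        columns=[f"c{i}" for i in range(5)] + [f"k{i}" for i in range(5)],
    )
    meta = pd.DataFrame(
        {"group": ["control"] * 5 + ["case"] * 5}, index=counts.columns
    )
    res = differential.nb_wald_test(
        counts, meta, pd.Series(1.0, index=counts.columns),
        independent_filtering=False,
    )
    np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-6)


def test_null_rejection_rate_near_nominal():
    coh = _null_cohort(seed=0)
    nf = differential.housekeeping_norm_factors(
        coh.counts, coh.truth.housekeeping_peaks
    )
    res = differential.nb_wald_test(coh.counts, coh.metadata, nf)
    rate = float((res["wald_p"] < 0.05).mean())
    assert 0.035 <= rate <= 0.065


def test_effect_recovery_with_housekeeping_anchor():
    cfg = simulate.SimulationConfig(n_peaks=5000, n_genes=1200, seed=11)
    coh = simulate.generate_cohort(cfg, simulate.generate_gene_models(cfg))
    nf = differential.housekeeping_norm_factors(
        coh.counts, coh.truth.housekeeping_peaks
    )
    res = differential.nb_wald_test(coh.counts, coh.metadata, nf)
    aff = res.loc[res.index.isin(coh.truth.affected_peaks)]
    assert aff["log2fc"].median() == pytest.approx(np.log2(1.5), abs=0.15)
    strong = aff[aff["mean_count"] > 100]
    assert strong["is_dar"].mean() >= 0.8


def test_scale_invariance_under_housekeeping_offsets():
    """Rescaling one sample's counts is absorbed by its housekeeping factor:
    estimates shift only through dispersion re-estimation (small)."""
    cfg = simulate.SimulationConfig(n_peaks=1000, n_genes=300, seed=8)
    coh = simulate.generate_cohort(cfg, simulate.generate_gene_models(cfg))
    hk = coh.truth.housekeeping_peaks
    nf = differential.housekeeping_norm_factors(coh.counts, hk)
    res = differential.nb_wald_test(coh.counts, coh.metadata, nf)
    scaled = coh.counts.copy()
    scaled[scaled.columns[2]] = scaled[scaled.columns[2]] * 3
    nf2 = differential.housekeeping_norm_factors(scaled, hk)
    res2 = differential.nb_wald_test(scaled, coh.metadata, nf2)
    assert float((res2["log2fc"] - res["log2fc"]).abs().median()) < 0.01
    assert float((res2["wald_p"] - res["wald_p"]).abs().median()) < 0.01
    sig1, sig2 = res["wald_p"] < 0.05, res2["wald_p"] < 0.05
    assert (sig1 == sig2).mean() > 0.97


def test_power_monotone_in_shift():
    rates = []
    for shift in (1.2, 1.5, 2.0):
        cfg = simulate.SimulationConfig(
            n_peaks=1500, n_genes=400, seed=13, global_shift=shift
        )
        coh = simulate.generate_cohort(cfg, simulate.generate_gene_models(cfg))
        nf = differential.housekeeping_norm_factors(
            coh.counts, coh.truth.housekeeping_peaks
        )
        res = differential.nb_wald_test(coh.counts, coh.metadata, nf)
        aff = res.loc[res.index.isin(coh.truth.affected_peaks)]
        rates.append(float(aff["is_dar"].fillna(False).mean()))
    assert rates[0] <= rates[1] <= rates[2]


def test_agreement_with_independent_deseq2_implementation():
    """Statistical cross-check against pydeseq2 on a sign-balanced two-group
    simulation: same estimates and essentially the same calls."""
    pydeseq2 = pytest.importorskip("pydeseq2")  # noqa: F841
    import warnings

    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    rng = np.random.default_rng(0)
    n, n_peaks = 8, 250
    mu = np.exp(rng.normal(5, 1, n_peaks))
    sign = rng.choice([-1.0, 1.0], n_peaks)
    beta = np.where(rng.random(n_peaks) < 0.3, sign, 0.0)
    grp = np.array([0] * n + [1] * n)
    m = mu[:, None] * 2.0 ** (beta[:, None] * grp[None, :])
    y = rng.poisson(rng.gamma(1 / 0.05, 0.05 * m))
    counts = pd.DataFrame(
        y, index=[f"p{i}" for i in range(n_peaks)],
        columns=[f"s{i}" for i in range(2 * n)],
    )
    meta = pd.DataFrame(
        {"group": np.where(grp == 1, "case", "control")}, index=counts.columns
    )
    mine = differential.nb_wald_test(
        counts, meta, pd.Series(1.0, index=counts.columns),
        independent_filtering=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~group",
                           quiet=True)
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["group", "case", "control"], quiet=True)
        stats.summary()
    ref = stats.results_df
    both = mine.join(ref[["log2FoldChange", "pvalue"]])
    assert np.corrcoef(both["log2fc"], both["log2FoldChange"])[0, 1] > 0.99
    assert (both["log2fc"] - both["log2FoldChange"]).abs().median() < 0.08
    agree = (both["wald_p"] < 0.01) == (both["pvalue"] < 0.01)
    assert agree.mean() >= 0.95


def test_rank_deficient_design_raises():
    counts = pd.DataFrame(
        np.random.default_rng(0).poisson(50, size=(20, 6)),
        columns=[f"s{i}" for i in range(6)],
    )
    meta = pd.DataFrame(
        {
            "group": ["control"] * 3 + ["case"] * 3,
            "dup": [0.0, 1.0, 0.0, 1.0, 1.0, 0.0],
            "dup2": [0.0, 2.0, 0.0, 2.0, 2.0, 0.0],
        },
        index=counts.columns,
    )
    with pytest.raises(ValueError, match="full rank"):
        differential.nb_wald_test(
            counts, meta, pd.Series(1.0, index=counts.columns),
            design=["dup", "dup2"],
        )


# --------------------------------------------------------------- MA summary


def test_ma_summary_null_median_near_zero():
    coh = _null_cohort(seed=4)
    nf = differential.housekeeping_norm_factors(
        coh.counts, coh.truth.housekeeping_peaks
    )
    res = differential.nb_wald_test(coh.counts, coh.metadata, nf)
    assert abs(differential.ma_summary(res)["median_log2fc"]) < 0.05


def test_ma_summary_shows_normalization_rationale():
    """Genome-wide shift (60% of peaks): the housekeeping anchor keeps the
    global median fold change, median-of-ratios flattens it."""
    cfg = simulate.SimulationConfig(
        n_peaks=3000, n_genes=800, seed=6, shift_fraction=0.6
    )
    coh = simulate.generate_cohort(cfg, simulate.generate_gene_models(cfg))
    hk = differential.housekeeping_norm_factors(
        coh.counts, coh.truth.housekeeping_peaks
    )
    mor = differential.median_of_ratios_factors(coh.counts)
    med_hk = differential.ma_summary(
        differential.nb_wald_test(coh.counts, coh.metadata, hk)
    )["median_log2fc"]
    med_mor = differential.ma_summary(
        differential.nb_wald_test(coh.counts, coh.metadata, mor)
    )["median_log2fc"]
    assert med_hk > 0.2
    assert abs(med_mor) < 0.5 * med_hk


# ----------------------------------------------------------------------- BH


def test_bh_worked_examples():
    np.testing.assert_allclose(
        differential.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
    )
    np.testing.assert_allclose(differential.bh_adjust([1.0, 1.0, 1.0]), 1.0)
    with pytest.raises(ValueError):
        differential.bh_adjust([0.5, 1.5])


def test_bh_matches_brute_force_oracle():
    rng = np.random.default_rng(5)
    for _ in range(200):
        m = int(rng.integers(1, 13))
        p = rng.uniform(size=m)
        np.testing.assert_allclose(
            differential.bh_adjust(p), brute_force_bh(p), atol=1e-12
        )


def test_bh_monotonicity_properties():
    rng = np.random.default_rng(6)
    p = rng.uniform(size=50)
    adj = differential.bh_adjust(p)
    assert (adj >= p - 1e-15).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-15).all()
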