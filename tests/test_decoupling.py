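"""Covariate adjustment of counts, promoter-expression coupling, the group
contrast across correlation thresholds, and gene-score resampling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from acetylscope import decoupling, differential, simulate


def _meta(n_per_group, batch=None):
    ids = [f"c{i}" for i in range(n_per_group)] + [
        f"k{i}" for i in range(n_per_group)
    ]
    meta = pd.DataFrame(
        {"group": ["control"] * n_per_group + ["case"] * n_per_group}, index=ids
    )
    if batch is not None:
        meta["batch"] = batch
    return meta


# ------------------------------------------------------------- adjust_counts


def test_adjust_no_covariates_returns_normalized_counts():
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.poisson(100, size=(50, 8)),
        index=[f"f{i}" for i in range(50)],
        columns=_meta(4).index,
    )
    nf = pd.Series(np.linspace(0.5, 2.0, 8), index=counts.columns)
    adj = decoupling.adjust_counts(counts, _meta(4), [], norm_factors=nf)
    np.testing.assert_allclose(adj.matrix, counts / nf, rtol=1e-12)
    assert adj.covariates_removed == []
    assert adj.group_preserved


def test_adjust_removes_injected_batch_effect_preserves_group():
    rng = np.random.default_rng(1)
    n = 10
    batch = np.tile(["b1", "b2"], n)
    meta = _meta(n, batch=batch)
    batch_mult = np.where(np.array(batch) == "b2", 2.0, 1.0)   # injected 2x
    group_mult = np.where(meta["group"] == "case", 1.5, 1.0)   # real signal
    mu = 200 * batch_mult * group_mult
    counts = pd.DataFrame(
        rng.poisson(np.tile(mu, (300, 1))),
        index=[f"f{i}" for i in range(300)], columns=meta.index,
    )
    adj = decoupling.adjust_counts(counts, meta, ["batch"])
    m = adj.matrix
    b2 = (np.array(batch) == "b2")
    log_batch_gap = np.log2(m.loc[:, b2].mean(axis=1) / m.loc[:, ~b2].mean(axis=1))
    assert abs(log_batch_gap.mean()) < 0.1 * 1.0  # <10% of the injected 1.0
    case = (meta["group"] == "case").to_numpy()
    log_group_gap = np.log2(
        m.loc[:, case].mean(axis=1) / m.loc[:, ~case].mean(axis=1)
    )
    assert log_group_gap.mean() == pytest.approx(np.log2(1.5), abs=0.1)


def test_adjust_is_a_fixed_point():
    rng = np.random.default_rng(2)
    n = 8
    batch = np.tile(["b1", "b2"], n)
    meta = _meta(n, batch=batch)
    mu = 150 * np.where(np.array(batch) == "b2", 1.8, 1.0)
    counts = pd.DataFrame(
        rng.poisson(np.tile(mu, (200, 1))),
        index=[f"f{i}" for i in range(200)], columns=meta.index,
    )
    once = decoupling.adjust_counts(counts, meta, ["batch"]).matrix
    twice = decoupling.adjust_counts(once, meta, ["batch"]).matrix
    rel = np.abs(twice - once) / (once + 1.0)
    assert float(rel.to_numpy().max()) < 0.05


def test_adjust_unknown_covariate_raises():
    counts = pd.DataFrame(np.ones((5, 8)), columns=_meta(4).index)
    with pytest.raises(ValueError, match="absent"):
        decoupling.adjust_counts(counts, _meta(4), ["nope"])


# -------------------------------------------- promoter-expression correlation


def _corr_inputs(chip_rows, rna_rows, n=5):
    meta = _meta(n)
    chip = pd.DataFrame(
        list(chip_rows.values()), index=list(chip_rows), columns=meta.index,
        dtype=float,
    )
    rna = pd.DataFrame(
        list(rna_rows.values()), index=list(rna_rows), columns=meta.index,
        dtype=float,
    )
    return chip, rna, meta


def test_linear_relation_gives_unit_correlation():
    rng = np.random.default_rng(3)
    x = rng.uniform(10, 100, size=10)
    chip, rna, meta = _corr_inputs(
        {"pk1": x}, {"g1": 2 * x + 7}
    )
    ann = pd.DataFrame({"peak_id": ["pk1"], "gene_id": ["g1"]})
    out = decoupling.promoter_expression_correlation(
        chip, rna, ann, meta["group"], log2_scale=False
    )
    assert out.loc["g1", "r_control"] == pytest.approx(1.0)
    assert out.loc["g1", "r_case"] == pytest.approx(1.0)
    assert out.loc["g1", "delta"] == pytest.approx(0.0)


def test_constant_expression_is_missing():
    rng = np.random.default_rng(4)
    chip, rna, meta = _corr_inputs(
        {"pk1": rng.uniform(10, 100, 10)}, {"g1": np.full(10, 5.0)}
    )
    ann = pd.DataFrame({"peak_id": ["pk1"], "gene_id": ["g1"]})
    out = decoupling.promoter_expression_correlation(
        chip, rna, ann, meta["group"], log2_scale=False
    )
    assert np.isnan(out.loc["g1", "r_control"])
    assert np.isnan(out.loc["g1", "delta"])


def test_max_over_promoters_picks_the_coupled_peak():
    """Two promoter peaks with latent coupling 0.9 vs 0.1: the reduction keeps
    the strongly coupled one in nearly all replicates."""
    rng = np.random.default_rng(5)
    n, hits = 15, 0
    trials = 40
    for _ in range(trials):
        z = rng.normal(size=2 * n)
        good = 0.9 * z + np.sqrt(1 - 0.81) * rng.normal(size=2 * n)
        bad = 0.1 * z + np.sqrt(1 - 0.01) * rng.normal(size=2 * n)
        meta = _meta(n)
        chip = pd.DataFrame(
            [100 + 20 * good, 100 + 20 * bad], index=["pk_good", "pk_bad"],
            columns=meta.index,
        )
        rna = pd.DataFrame([200 + 40 * z], index=["g1"], columns=meta.index)
        ann = pd.DataFrame(
            {"peak_id": ["pk_good", "pk_bad"], "gene_id": ["g1", "g1"]}
        )
        out = decoupling.promoter_expression_correlation(
            chip, rna, ann, meta["group"], log2_scale=False
        )
        hits += out.loc["g1", "peak_control"] == "pk_good"
    assert hits >= 0.9 * trials


def test_max_reduction_never_below_single_promoter():
    rng = np.random.default_rng(6)
    meta = _meta(6)
    chip = pd.DataFrame(
        rng.uniform(50, 150, size=(3, 12)),
        index=["pk1", "pk2", "pk3"], columns=meta.index,
    )
    rna = pd.DataFrame(
        rng.uniform(100, 300, size=(1, 12)), index=["g1"], columns=meta.index
    )
    ann = pd.DataFrame(
        {"peak_id": ["pk1", "pk2", "pk3"], "gene_id": ["g1"] * 3}
    )
    out = decoupling.promoter_expression_correlation(
        chip, rna, ann, meta["group"], log2_scale=False
    )
    ctrl = (meta["group"] == "control").to_numpy()
    singles = [
        np.corrcoef(chip.loc[pk].to_numpy()[ctrl], rna.loc["g1"].to_numpy()[ctrl])[0, 1]
        for pk in chip.index
    ]
    assert out.loc["g1", "r_control"] >= max(singles) - 1e-12


# ------------------------------------------------------------ threshold sweep


def _simulated_correlations(seed, r_control, r_case, n_genes=600, n=15):
    cfg = simulate.SimulationConfig(
        n_peaks=2 * n_genes, n_genes=n_genes, n_samples_per_group=n, seed=seed,
        coupling_r_control=r_control, coupling_r_case=r_case,
    )
    genes = simulate.generate_gene_models(cfg)
    coh = simulate.generate_cohort(cfg, genes)
    prom = simulate.promoter_counts_by_gene(coh, genes)
    expr, _ = simulate.generate_expression(cfg, genes, prom, coh.metadata["group"])
    adj_chip = decoupling.adjust_counts(
        prom, coh.metadata, [], norm_factors=differential.total_count_factors(coh.counts)
    )
    adj_rna = decoupling.adjust_counts(
        expr, coh.metadata, [], norm_factors=differential.total_count_factors(expr)
    )
    ann = pd.DataFrame({"peak_id": prom.index, "gene_id": prom.index})
    return decoupling.promoter_expression_correlation(
        adj_chip.matrix, adj_rna.matrix, ann, coh.metadata["group"]
    )


def test_sweep_detects_decoupling_and_gap_grows_with_threshold():
    cors = _simulated_correlations(seed=1, r_control=0.6, r_case=0.0)
    sweep = decoupling.threshold_sweep(cors, [0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
    at_03 = sweep[sweep["threshold"] == 0.3].iloc[0]
    assert at_03["median_control"] > 0.4
    assert abs(at_03["median_case"]) < 0.1
    assert at_03["p"] < 0.01
    gaps = sweep["median_control"] - sweep["median_case"]
    assert (np.diff(gaps) >= -0.02).all()  # non-decreasing up to noise


def test_sweep_null_when_coupling_equal():
    cors = _simulated_correlations(seed=2, r_control=0.5, r_case=0.5, n_genes=300)
    sweep = decoupling.threshold_sweep(cors, [0.3])
    assert sweep["p"].iloc[0] > 0.05
    assert abs(sweep["shift"].iloc[0]) < 0.05


def test_sweep_flags_unstable_thresholds():
    cors = pd.DataFrame(
        {"r_control": [0.9, 0.8, 0.1], "r_case": [0.85, 0.7, 0.0]},
        index=["g1", "g2", "g3"],
    )
    with pytest.warns(UserWarning):
        sweep = decoupling.threshold_sweep(cors, [0.5])
    assert sweep["unstable"].iloc[0]


# ------------------------------------------------------ gene score resampling


def test_gsr_extreme_set_achieves_minimum_p():
    scores = pd.Series(np.arange(100, dtype=float), index=[f"g{i}" for i in range(100)])
    out = decoupling.gene_score_resampling(
        scores, [f"g{i}" for i in range(5)], n_resamples=999, seed=0
    )
    assert out["p"] == pytest.approx(1.0 / 1000.0)


def test_gsr_matches_exhaustive_enumeration():
    scores = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0],
                       index=["a", "b", "c", "d", "e"])
    gene_set = ["a", "c"]
    observed = scores[gene_set].mean()
    null = [
        scores[list(c)].mean() for c in itertools.combinations(scores.index, 2)
    ]
    p_exact = np.mean([m <= observed for m in null])
    out = decoupling.gene_score_resampling(scores, gene_set, n_resamples=20_000,
                                           seed=1)
    assert out["p"] == pytest.approx(p_exact, abs=0.02)


def test_gsr_uniform_under_random_sets():
    rng = np.random.default_rng(7)
    scores = pd.Series(rng.normal(size=300), index=[f"g{i}" for i in range(300)])
    ps = []
    for i in range(200):
        gene_set = rng.choice(scores.index, size=10, replace=False)
        ps.append(
            decoupling.gene_score_resampling(
                scores, gene_set, n_resamples=1000, seed=i
            )["p"]
        )
    assert kstest(ps, "uniform").pvalue > 0.01


def test_gsr_rejects_bad_sets():
    scores = pd.Series([1.0, 2.0], index=["a", "b"])
    with pytest.raises(ValueError):
        decoupling.gene_score_resampling(scores, [], n_resamples=10)
    with pytest.raises(ValueError):
        decoupling.gene_score_resampling(scores, ["a", "b"], n_resamples=10)
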