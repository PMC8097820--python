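"""End-to-end orchestration: simulate -> annotate -> MSP -> differential ->
meta-analysis -> regulatory context -> decoupling.

Each stage is a thin composition of the module functions; the analysis
drivers and the acceptance checks run these rather than re-wiring the stages
themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import composition, context, decoupling, differential, genomic, meta
from .simulate import Cohort, SimulationConfig, Study, generate_study, \
    promoter_counts_by_gene

DEFAULT_THRESHOLDS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


def default_study_config(seed: int = 11) -> SimulationConfig:
    """The standard study conditions used by the analysis drivers: two
    cohorts, 5000 peaks, 10 subjects per group, 1.5-fold hyperacetylation on
    30% of case peaks, activator-site enrichment with mild deacetylase
    depletion on affected peaks, a GC deficit on affected peaks, and a
    negatively coupled (mitochondrial-like) gene subset."""
    return SimulationConfig(
        seed=seed,
        n_negative_coupling_genes=40,
        binding_deacetylase_depletion=2.0,
        gc_affected=0.40,
    )


@dataclass
class CohortAnalysis:
    name: str
    peaks: pd.DataFrame
    annotations: pd.DataFrame
    msp: pd.DataFrame
    norm_factors: pd.Series
    outliers: list
    results: pd.DataFrame
    ma: dict
    binding: pd.DataFrame
    binding_contrast: dict
    hyper_model: pd.DataFrame
    gc: dict | None
    correlations: pd.DataFrame
    sweep: pd.DataFrame
    gsr: dict | None = None


@dataclass
class StudyAnalysis:
    study: Study
    cohorts: dict = field(default_factory=dict)
    peakset_comparison: dict | None = None
    pairs: pd.DataFrame | None = None
    replication: dict | None = None
    egl_fit: pd.DataFrame | None = None


def cohort_msp(study: Study, coh: Cohort) -> pd.DataFrame:
    """Reference DARs -> marker-site assignment -> per-type MSP scores."""
    from .simulate import generate_reference_counts

    ref_counts, ref_labels = generate_reference_counts(
        study.config, coh.peaks, coh.truth
    )
    dars = composition.reference_dars(ref_counts, ref_labels)
    ann = genomic.annotate_peaks(coh.peaks, study.genes, scheme="msp_window")
    sets = composition.assign_marker_sites(dars, ann, study.marker_genes)
    return composition.msp_table(coh.counts, sets)


def analyze_cohort(study: Study, name: str,
                   drop_outliers: bool = True) -> CohortAnalysis:
    coh = study.cohorts[name]
    canonical = {f"chr{i + 1}" for i in range(len(study.config.genome_length))}
    peaks = genomic.filter_peaks(coh.peaks, canonical_chroms=canonical,
                                 max_detection_p=1e-7)
    counts = coh.counts.loc[peaks["peak_id"]]
    annotations = genomic.annotate_peaks(peaks, study.genes, scheme="structural")
    msp = cohort_msp(study, coh)

    hk_ids = differential.select_housekeeping_peaks(peaks, study.genes)
    norm_factors = differential.housekeeping_norm_factors(counts, hk_ids)
    outliers = differential.detect_outliers(counts) if drop_outliers else []
    kept = [s for s in counts.columns if s not in outliers]
    counts = counts[kept]
    metadata = coh.metadata.loc[kept].copy()
    metadata["oligo_msp"] = msp.loc[kept, "oligodendrocyte"]
    norm_factors = differential.housekeeping_norm_factors(counts, hk_ids)

    results = differential.nb_wald_test(
        counts, metadata, norm_factors,
        design=["age", "sex", "pmi", "batch", "oligo_msp"],
    )
    ma = differential.ma_summary(results)

    binding = context.count_binding(peaks, study.binding[name])
    dar_flags = results["is_dar"].fillna(False) & (results["log2fc"] > 0)
    binding_contrast = context.binding_ratio_contrast(
        binding, dar_flags, scope="all_genes"
    )
    ph = pd.Series(
        context.p_hyper(results["wald_p"].fillna(1.0), results["log2fc"]),
        index=results.index,
    )
    implicated_genes = set(study.genes.loc[study.genes["is_implicated"], "gene_id"])
    with_gene = annotations.dropna(subset=["gene_id"])
    implicated_peaks = pd.Series(False, index=results.index)
    imp = with_gene.loc[with_gene["gene_id"].isin(implicated_genes), "peak_id"]
    implicated_peaks[implicated_peaks.index.isin(set(imp))] = True
    hyper_model = context.hyperacetylation_model(binding, ph, implicated_peaks)

    from .simulate import generate_sequences

    seqs = generate_sequences(study.config, peaks, coh.truth)
    dar_pk = peaks[peaks["peak_id"].isin(results.index[dar_flags])]
    bg_pk = peaks[~peaks["peak_id"].isin(results.index[dar_flags])]
    gc = (
        context.gc_contrast(dar_pk, bg_pk, seqs, n_draws=3,
                            seed=study.config.seed)
        if len(dar_pk) >= 10
        else None
    )

    prom = promoter_counts_by_gene(coh, study.genes)
    prom = prom[kept]
    expr = study.expression[name][kept]
    adj_chip = decoupling.adjust_counts(
        prom, metadata, ["age", "sex", "pmi", "batch", "oligo_msp"],
        norm_factors=differential.total_count_factors(counts).loc[kept],
    )
    adj_rna = decoupling.adjust_counts(
        expr, metadata, ["age", "sex", "pmi", "batch", "oligo_msp"],
        norm_factors=differential.total_count_factors(expr),
    )
    gene_ann = pd.DataFrame({"peak_id": prom.index, "gene_id": prom.index})
    correlations = decoupling.promoter_expression_correlation(
        adj_chip.matrix, adj_rna.matrix, gene_ann, metadata["group"]
    )
    sweep = decoupling.threshold_sweep(correlations, list(DEFAULT_THRESHOLDS))

    gsr = None
    neg = coh.truth.negative_coupling_genes & set(correlations.index)
    scores = correlations["delta"].dropna()
    if len(neg) >= 3 and len(scores) > 2 * len(neg):
        gsr = decoupling.gene_score_resampling(
            scores, sorted(neg), n_resamples=2000, seed=study.config.seed
        )

    return CohortAnalysis(
        name=name, peaks=peaks, annotations=annotations, msp=msp,
        norm_factors=norm_factors, outliers=outliers, results=results, ma=ma,
        binding=binding, binding_contrast=binding_contrast,
        hyper_model=hyper_model, gc=gc, correlations=correlations,
        sweep=sweep, gsr=gsr,
    )


def dar_gene_sets(analysis: CohortAnalysis) -> tuple[set, set]:
    """(DAR peak ids, DAR-bearing gene ids) for one cohort."""
    dars = set(analysis.results.index[analysis.results["is_dar"].fillna(False)])
    ann = analysis.annotations.dropna(subset=["gene_id"])
    genes = set(ann.loc[ann["peak_id"].isin(dars), "gene_id"])
    return dars, genes


def run_study_analysis(config: SimulationConfig | None = None,
                       study: Study | None = None) -> StudyAnalysis:
    """The full two-cohort analysis on a synthetic study."""
    if study is None:
        study = generate_study(config or SimulationConfig())
    out = StudyAnalysis(study=study)
    for name in study.cohorts:
        out.cohorts[name] = analyze_cohort(study, name)
    a, b = out.cohorts["A"], out.cohorts["B"]
    out.peakset_comparison = genomic.peakset_comparison(
        a.peaks, b.peaks, genome_size=int(sum(study.config.genome_length))
    )
    out.pairs = meta.harmonize(
        a.annotations, b.annotations, a.results, b.results, a.peaks, b.peaks
    )
    dars_a, genes_a = dar_gene_sets(a)
    dars_b, genes_b = dar_gene_sets(b)
    universe = (
        set(a.annotations.dropna(subset=["gene_id"])["gene_id"])
        & set(b.annotations.dropna(subset=["gene_id"])["gene_id"])
    )
    out.replication = meta.replication_summary(
        out.pairs, genes_a, genes_b, dars_a, dars_b, universe
    )
    egl = genomic.effective_gene_length(study.genes)
    n_regions = out.pairs.groupby("gene_id").size()
    implicated = study.genes.set_index("gene_id")["is_implicated"]
    stats = out.pairs.assign(
        p=out.pairs["meta_p"],
        egl=egl.reindex(out.pairs["gene_id"]).to_numpy(),
        n_regions=n_regions.reindex(out.pairs["gene_id"]).to_numpy(),
        is_implicated=implicated.reindex(out.pairs["gene_id"]).to_numpy(),
    )
    hyper = stats[(stats["lfc_A"] > 0) & (stats["lfc_B"] > 0)]
    out.egl_fit = meta.egl_model(hyper) if len(hyper) > 30 else None
    return out
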