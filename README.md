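# acetylscope

Cell-composition-aware differential histone-acetylation analysis for
case/control ChIP-seq studies of bulk brain tissue, with two-cohort
replication, regulatory-context statistics and promoter-mark/expression
decoupling — exercised end to end on a synthetic two-cohort generator with
known ground truth.

## The problem

Genome-wide gains of an activating histone mark (e.g. H3K27ac) in a disease
group break the assumptions behind standard count normalization and are
confounded by cell-composition differences in bulk tissue.  This package
implements the full analysis chain such a study needs:

1. **Genomic core** — BED/TSV/FASTA I/O, 0-based half-open interval algebra,
   peak filtering (blacklist, canonical chromosomes, detection p ≤ 1e-7),
   strand-aware peak-to-gene annotation (promoter / 1to5kb / 5'UTR / exon /
   intron / intergenic, plus the TSS−5kb→5'UTR "msp window"), and peak-set
   comparison (counts, % unique, % genome covered).
2. **Cell composition** — marker site profiles (MSPs): reference
   differential sites from sorted nuclei (|FC| > 4, mean count > 1000),
   assignment to cell types via marker gene lists, and per-sample PC1 scores
   over each type's marker sites as relative-abundance covariates.
3. **Differential acetylation** — per-sample normalization factors anchored
   on saturated housekeeping-gene peaks (so a genome-wide shift is measured,
   not normalized away), a median-correlation outlier screen, and a
   vectorized negative-binomial Wald test with Cox–Reid dispersion
   estimation, trend shrinkage and BH-adjusted calls
   (DAR = adjusted p < 0.05).
4. **Meta-analysis / replication** — common peak pairs across cohorts keyed
   by (gene, annotation category) with minimum-midpoint-distance matching,
   Fisher meta-p (chi-square, 4 df), replicated genes/DARs with explicit
   hypergeometric universes, and the effective-gene-length regression.
5. **Regulatory context** — activator vs deacetylase binding-site counts per
   peak, the ln((act+0.01)/(deac+0.01)) contrast between DARs and non-DARs
   (KS / rank-sum), the one-sided hyperacetylation fold
   p_hyper = p/2 (LFC ≥ 0) | 1 − p/2 (LFC < 0) and its linear model, and GC
   content against a length-matched background.
6. **Decoupling** — covariate-adjusted counts (group effect preserved),
   per-gene Pearson correlation between promoter acetylation and expression
   with a max-over-promoters reduction, a threshold sweep of the group
   contrast (Wilcoxon + Hodges–Lehmann shift), and gene-score resampling for
   user-supplied gene sets on ΔCor = r_case − r_control.
7. **Synthetic cohorts** — a deterministic generator producing both cohorts
   (peaks, NB counts, metadata, sorted-cell reference, marker lists, binding
   tracks, sequences, expression) with every injected effect recorded.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
from acetylscope import pipeline, simulate

cfg = pipeline.default_study_config()       # two cohorts, 5000 peaks, 10+10
sa = pipeline.run_study_analysis(cfg)

ca = sa.cohorts["A"]
print(len(ca.peaks), int(ca.results["is_dar"].sum()),
      round(ca.ma["median_log2fc"], 3))
print(sa.replication["n_replicated_genes"],
      f"{sa.replication['gene_overlap_p']:.2e}")
print(ca.sweep[ca.sweep.threshold == 0.3].round(3).to_string(index=False))
```

prints

```
4902 1092 0.11
113 1.81e-21
 threshold  n_genes  median_control  median_case  shift   p  unstable
       0.3     1047           0.558        0.078 -0.452 0.0     False
```

Reading: of 4902 filtered peaks in cohort A, 1092 are called DARs and the
genome-wide median log2 fold change (+0.11) reflects the injected
case-group hyperacetylation that housekeeping anchoring preserves; 113 genes
carry DARs in both cohorts, far beyond the hypergeometric expectation
(p ≈ 2e-21) because half of the truly affected genes are shared; and at the
|r| > 0.3 threshold the control group's promoter–expression coupling
(median r = 0.56) collapses in cases (median 0.08, Wilcoxon p ≈ 0), the
simulated decoupling.

The numbered drivers under `analysis/` run the same stages as a narrated
sequence (`01_simulate_cohorts.py` … `07_decoupling.py`), each writing its
tables under `results/`.

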