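# Methods

## Scope and model of the data

`acetylscope` implements a complete desk-scale analysis of case/control
histone-acetylation (H3K27ac-style) ChIP-seq studies in bulk brain tissue,
from called peak coordinates and reads-in-peaks (RiP) count matrices onward.
Raw read processing and peak calling are out of scope; the pipeline's atom is
a half-open genomic interval with a detection p-value and per-sample counts.

Counts for peak *f* in sample *s* are modeled as negative binomial (NB2),

    y_fs ~ NB(mu_fs, alpha_f),   log mu_fs = x_s' beta_f + log c_s,

with a shared design matrix across peaks (intercept, case indicator with
control as reference, and nuisance covariates: age, sex, post-mortem
interval, batch, and the oligodendrocyte marker-site profile) and a
per-sample normalization factor c_s entering as an offset.  log2 fold change
> 0 always means higher in cases.

## Normalization: why housekeeping anchoring

Median-of-ratios or total-count factors assume that most features are
unchanged between groups.  When one group is globally hyperacetylated that
assumption fails: the shift is absorbed into the size factors and the
estimated fold changes flatten toward zero.  The pipeline instead anchors
the factors on *saturated housekeeping peaks* — peaks covering at least 80%
of a housekeeping gene's footprint (threshold configurable), regions already
full of the mark and hence with little biological variance:

    c_s = HK_RiP_s / geometric_mean_s(HK_RiP_s).

The anchor has a cost: with a handful of housekeeping peaks the factors
carry sampling noise (standard deviation of the group-mean offset is roughly
sigma_HK * sqrt(2/n)), which appears as a small cohort-level shift of all
fold changes.  The normalization contrast in the differential stage (the
same data fitted under both factor types) quantifies what anchoring
preserves: under a genome-wide shift the housekeeping-normalized genome-wide
median log2FC stays positive while the median-of-ratios one collapses to ~0.
`median_of_ratios_factors` and `total_count_factors` are provided for
exactly this comparison (and for matrices, like RNA counts, where the
no-global-shift assumption is fine).

## NB fitting and the Wald test

The fitting engine (`nbglm`) exploits the fact that the design matrix is
shared across features: each IRLS step is a single batched linear solve over
all peaks at once.  Dispersion is estimated in three stages, mirroring
standard practice for small-sample RNA/ChIP count models:

1. method-of-moments start, batched IRLS for initial means;
2. per-peak Cox–Reid adjusted profile maximum likelihood for alpha_f
   (grid over log alpha in [1e-8, 20], 25 points, parabolic refinement) —
   the CR term (−½ log det X'WX) corrects the downward bias of plain ML
   when p coefficients are fit to n≈20 samples;
3. shrinkage toward a smooth trend: lowess of log alpha on log mean
   (frac = 0.4), combined on the log scale with weight 0.5 (configurable;
   0 = pure per-peak ML, 1 = pure trend).

Inference on the group coefficient is a Wald test from the observed Fisher
information.  The reference distribution is t with n − p degrees of freedom
rather than normal: at n = 20 the asymptotic z reference is visibly
anticonservative (raw rejection ≈ 0.06 at nominal 0.05 in null simulations),
while the t reference keeps the null rejection rate at 0.04–0.05.  Peaks
whose IRLS did not converge, or with all-zero counts, get a missing p-value
and are excluded from multiple-testing.

Multiplicity is controlled by Benjamini–Hochberg, preceded by optional
independent filtering on the mean normalized count (threshold chosen over a
20-point quantile grid to maximize discoveries, ties to the weakest filter;
configurable off).  A DAR (differentially acetylated region) is a peak with
adjusted p < 0.05.

The engine is statistically, not numerically, aligned with DESeq2: a test
cross-checks estimates and calls against pydeseq2 on a sign-balanced
simulation (fold-change correlation > 0.99, ≥95% agreement of calls at
p < 0.01), but no attempt is made to reproduce another package's numerics
bit for bit.

## Outlier screening

Per sample: the median Spearman correlation to all other samples on
log2(CPM+1); samples below median − 3·MAD of those medians are flagged.  The
MAD is scaled by 1.4826 (the normal-consistent estimator — "3 MADs" ≈ 3
standard deviations for Gaussian spread) and floored (1e-3) so degenerate,
near-identical sample sets flag nothing.  Without the scaling the band is
narrow enough to flag samples that are merely extreme in cell composition;
with it, the screen still catches a genuinely corrupted (label-permuted)
sample.  The rule is this package's own choice of screen; the threshold (3)
and the statistic are configurable.

## Cell composition (MSP)

Bulk brain chromatin mixes cell types, and composition is typically the
dominant variance component.  The marker-site-profile estimator:

1. **Reference differential sites.**  From sorted-nuclei reference counts
   (NeuN+ vs NeuN−), CPM-normalize, keep sites with |class-mean fold
   change| > 4 and overall mean normalized count > 1000; a +0.5 floor
   handles zero class means (flagged).
2. **Marker assignment.**  Sites are annotated to genes through the
   *msp_window* scheme — the span from 5 kb upstream of the TSS to the end
   of the 5'UTR, strand-adjusted.  A site annotated to marker genes of
   exactly one cell type joins that type's marker-site set; sites touching
   marker genes of several types are dropped (sets stay disjoint).
   Direction consistency is enforced: neuronal marker sites must be
   NeuN+-up, glial sites NeuN−-up.
3. **Profile.**  On the bulk matrix: CPM over total RiP, log2(CPM+1), PCA
   across samples restricted to the type's marker sites; the MSP is the PC1
   score, sign-oriented to correlate positively with the mean marker
   signal.  Raw scores feed downstream models; a [0,1] min–max rescale over
   the analyzed samples is provided for display.  `compute_mgp` applies the
   identical algorithm to expression matrices (marker genes instead of
   marker sites).

In simulation (50 marker sites, 20 samples, composition uniform on
[0.2, 0.6]), the MSP correlates with the true oligodendrocyte proportion at
median r ≈ 0.95 over 20 seeds.

## Two-cohort harmonization and replication

Independently called peak-sets do not align coordinate-wise, so cohorts are
paired through annotation: for every (gene, structural category) key present
in both cohorts, one peak per cohort forms a *common peak pair*.  With
several candidates on either side, the one-to-one assignment minimizing
total midpoint distance is used (Hungarian algorithm); leftovers stay
unpaired and no peak joins two pairs.  Evidence is combined by Fisher's
method on the two raw per-cohort p-values (combining adjusted p-values would
be incoherent), X² = −2(ln p_A + ln p_B) against chi-square with 4 df, BH
across pairs.  Replication is quantified at two levels — genes with ≥1 DAR
in both cohorts, and pairs that are DARs in both cohorts — each with an
upper-tail hypergeometric test whose universe must be passed explicitly and
is always reported alongside the p-value.

The gene-length model regresses −log10(p) (meta or per-cohort) on the
disease-implicated-gene flag, log10 effective gene length (gene span plus
1 kb upstream of the TSS) and the number of regions per gene, by OLS with
95% CIs, separately for concordantly hyper- and hypoacetylated pairs
(discordant pairs excluded).

## Regulatory context

Binding-site tracks (an activator, p300-like, and one or more deacetylase,
non-SIRT1-HDAC-like, factors) are counted per peak as the number of
overlapping intervals (≥1 bp rule; counts, not bp coverage).  Non-activator
factors are summed.  Peaks with no site of either kind are excluded.  The
per-peak balance is ln((activator + 0.01)/(deacetylase + 0.01)); the
pseudocount follows the printed form of the statistic.  DAR vs non-DAR
contrasts use a two-sided two-sample Kolmogorov–Smirnov test genome-wide and
a two-sided Wilcoxon rank-sum on the small implicated-gene subset.  The
hyperacetylated-DAR class is DARs with positive log2FC (the hypoacetylated
class is typically too small to contrast).

One-sided hyperacetylation evidence folds the two-sided p with the fold
direction: p_hyper = p/2 if LFC ≥ 0, else 1 − p/2; so
p_hyper(p, +) + p_hyper(p, −) = 1.  The association model is OLS of
−log10(p_hyper) on activator count + deacetylase count + implicated flag,
with a gene-level variant that first sums counts over each gene's peaks.

GC content of DARs is contrasted against a background matched on region
length: nearest-length sampling without replacement (relative tolerance
10%, widened with a warning when a stratum runs dry), repeated over draws
with the median difference and median rank-sum p reported.  GC is
(G+C)/(A+C+G+T) with Ns excluded; empty or all-N sequences are NaN.

## Promoter-acetylation / expression decoupling

1. **Covariate adjustment.**  Both count matrices are adjusted by refitting
   the NB model (group + covariates, log factor offset) and mapping each
   observation through y · exp((x_adj − x)'beta)/c_s, where x_adj sets
   dummy covariates to the reference level and centered continuous
   covariates to zero — predicted-plus-residual on the log scale.  The group
   effect is never removed; with no covariates the operation reduces exactly
   to normalized counts.
2. **Per-gene coupling.**  Pearson correlation between the adjusted promoter
   signal and adjusted expression across each group's samples, on the
   log2(x+1) scale (the scale on which the NB log-linear signal is additive;
   the raw-count scale is available via `log2_scale=False`).  With several
   promoter peaks, each is correlated and the maximum signed r is kept per
   group independently (maximum |r| available by flag; ties break by genomic
   order).  Zero-variance vectors yield missing correlations, excluded
   pairwise.
3. **Threshold sweep.**  For each absolute-correlation threshold t, genes
   with |r| > t in at least one group are kept; the two groups' correlation
   distributions are compared by a two-sided Wilcoxon rank-sum, reporting
   group medians, the Hodges–Lehmann location shift (case − control) and the
   retained gene count (< 10 flagged unstable).
4. **Gene-score resampling.**  Gene sets are scored against the ΔCor
   (= r_case − r_control) distribution: observed statistic is the set's mean
   score, the null is the mean of random same-size sets, and the empirical
   p is (1 + #{null ≤ observed})/(n_resamples + 1) under "low is hit" (more
   negative ΔCor = more decoupled).

Normalization matters here for a non-obvious reason: library-size variation
is shared across all genes within a matrix, so leaving it in both matrices
induces one random correlation between the two libraries' depth vectors that
every gene inherits — a per-dataset offset of the whole correlation
distribution.  Adjusted counts are therefore always computed on normalized
scale (total-count factors by default).

## Synthetic two-cohort generator

The generator is first-class, tested code and defines the study conditions:

- **Genome and genes.**  Two chromosomes (60 + 40 Mb), 1200 non-overlapping
  strand-aware genes with Pareto(1.1)-tailed lengths (min 2 kb, cap 2 Mb;
  max/median > 10 at n = 2000), 1–8 exons, a 5'UTR of 100–1000 bp inside the
  first exon; labeled subsets: 5 housekeeping genes (short, each covered by
  one saturated peak), 60 disease-implicated genes, 25 marker genes per cell
  type (neuron, oligodendrocyte).
- **Peaks.**  ~5000 per cohort: one saturated peak per housekeeping gene,
  one promoter-spanning marker peak per marker gene, one promoter peak per
  gene (20% get a second), the rest gene-body (60%, length-weighted) and
  intergenic; widths lognormal with median ~800 bp; detection p-values
  mostly far below the 1e-7 filter with a 2% weak fraction to exercise it.
- **Counts.**  NB via gamma–Poisson with dispersion 0.05 (housekeeping
  0.005), base means lognormal (ln-median ≈ 150), per-sample library factors
  lognormal (sd 0.3).  Case samples receive a multiplicative 1.5-fold shift
  on 30% of peaks (housekeeping and marker peaks protected).  Marker-site
  means mix convexly with the per-sample composition: for oligodendrocyte
  sites mu ∝ 8·p + (1−p), p ~ U(0.2, 0.6); the same additivity the MSP
  estimator assumes.  Metadata (age, sex, PMI, batch) are independent of
  group unless confounding is requested explicitly.
- **Two cohorts.**  Cohort B's affected peaks are drawn first from peaks on
  a shared half of cohort A's affected genes, then topped up at random, so a
  controlled fraction of truly affected genes replicates.
- **Expression.**  Per gene and group, the latent log2 expression mean is
  r·z + sqrt(1−r²)·noise where z is the within-group standardized
  log2(CPM+1) of the gene's promoter peak and r the group's coupling target
  (0.6 controls, 0.0 cases by default; an optional subset gets negative
  coupling in cases, emulating the mitochondrial-gene observation).  NB
  sampling (dispersion 0.02, depth ~200) attenuates the realized correlation
  only mildly.
- **Binding sites and sequences.**  Poisson site counts per peak, with the
  activator rate multiplied (and optionally the deacetylase rate divided) by
  an enrichment factor on affected peaks; i.i.d. sequences with
  class-specific GC.
- **Determinism.**  All randomness flows through per-component
  `numpy.random.SeedSequence` streams derived from the single config seed;
  identical configs give byte-identical output files.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: spatial read autocorrelation and fragment-level
coverage, peak-calling artifacts, GC- or mappability-dependent counting
bias, correlated dispersion across neighboring peaks, more than two cell
types, batch-by-group interactions, and annotation error.  Recovery results
here demonstrate internal consistency of the estimators under their own
model, not field performance.

## Numerical choices and edge cases

- Coordinates are 0-based half-open everywhere; overlap is ≥1 bp; a peak
  spanning several categories yields several annotation records.
- Promoter = 1 kb upstream of the TSS (configurable), strand-adjusted and
  clipped at the chromosome start; the msp window is strand-adjusted too.
- IRLS: linear-predictor clip at ±30, ridge 1e-10 on the normal equations,
  convergence at max |Δbeta| < 1e-8, 50 iterations.
- Fisher meta: p = 0 clamps to the smallest positive float.
- Hypergeometric tests use the exact distribution (verified against subset
  enumeration for all universes ≤ 12).
- The scale-invariance of the differential stage under per-sample count
  rescaling is exact for the offset absorption but approximate through
  dispersion re-estimation; in tests a 3× rescale moves median |log2FC| by
  < 0.01.
- Problem sizes in tests and in the acceptance script (5000 peaks, 10–15
  samples per group, 2000 genes, 20-seed replicates) are the package's
  standard desk-scale study conditions.

## Known limitations

- The Wald-with-t reference is a pragmatic small-sample correction, not an
  exact test; calibration was verified at n = 20 and will drift for much
  smaller designs.
- Housekeeping anchoring inherits the sampling noise of a small anchor set;
  cohort-level fold-change offsets of ±0.05 log2 are expected with ~5
  anchor peaks and appear in the two-cohort driver output.
- The threshold sweep's Wilcoxon treats genes as independent although all
  correlations within a group share samples; with ≤10 samples per group the
  contrast is mildly anticonservative (null significance ~8% at 0.05), and
  well calibrated at n = 15.
- Gene-score resampling does not correct for gene multifunctionality, and
  GO-database enrichment is out of scope; sets are user-supplied.
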