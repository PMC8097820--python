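"""Synthetic two-cohort generator with known ground truth.

Emulates the statistical structure of a bulk-brain H3K27ac ChIP-seq case /
control study: negative-binomial reads-in-peaks with sample-specific library
sizes, a multiplicative genome-wide hyperacetylation shift on a fraction of
case-group peaks, saturated low-variance housekeeping peaks, cell-type marker
sites whose means mix with the per-sample cell composition, two cohorts
sharing a configurable fraction of truly affected genes, binding-site tracks
whose density co-varies with the injected shift, peak sequences with
class-specific GC content, and expression counts whose coupling to promoter
acetylation differs between groups.

Counts follow the same NB log-linear mean model the differential stage
assumes (library offset x group shift x composition mixture), so parameter
recovery is well-posed.  Every injected effect is recorded in
:class:`SyntheticTruth`.  Identical configs (same seed) give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genomic import annotate_peaks

CELL_TYPES = ("neuron", "oligodendrocyte")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    Defaults reflect a desk-scale version of a two-group bulk brain study:
    ~5,000 consensus peaks, 10 subjects per group, a 1.5-fold hyperacetylation
    shift on 30% of peaks in cases, moderate biological dispersion (0.05) and
    ~35% spread in library size.
    """

    genome_length: tuple = (60_000_000, 40_000_000)
    n_genes: int = 1200
    n_peaks: int = 5000
    n_samples_per_group: int = 10
    global_shift: float = 1.5
    shift_fraction: float = 0.3
    shared_gene_fraction: float = 0.5
    nb_dispersion: float = 0.05
    libsize_log_sd: float = 0.3
    composition_range: tuple = (0.2, 0.6)
    coupling_r_control: float = 0.6
    coupling_r_case: float = 0.0
    seed: int = 0
    # gene / peak architecture
    n_housekeeping: int = 5
    n_implicated: int = 60
    n_marker_genes_per_type: int = 25
    min_gene_length: int = 2000
    gene_length_tail: float = 1.1        # Pareto tail exponent
    max_gene_length: int = 2_000_000
    second_promoter_fraction: float = 0.2
    weak_peak_fraction: float = 0.02     # detection p above the 1e-7 filter
    peak_mean_log_mu: float = 5.0        # ln scale: median base mean ~150
    peak_mean_log_sd: float = 1.0
    housekeeping_mean: float = 5000.0
    housekeeping_dispersion: float = 0.005
    marker_contrast: float = 8.0
    # binding-site tracks
    binding_rate_activator: float = 1.0
    binding_rate_deacetylase: float = 1.0
    binding_enrichment: float = 3.0
    binding_deacetylase_depletion: float = 1.0
    # sequences
    gc_background: float = 0.50
    gc_affected: float = 0.50
    # expression
    expression_mean_log2: float = 7.6
    expression_log2_sd: float = 1.0
    expression_dispersion: float = 0.02
    expression_libsize_log_sd: float = 0.2
    latent_log2_sd: float = 1.0
    n_negative_coupling_genes: int = 0
    coupling_r_negative: float = -0.5
    confound_batch_with_group: bool = False

    def validate(self) -> None:
        fractions = {
            "shift_fraction": self.shift_fraction,
            "shared_gene_fraction": self.shared_gene_fraction,
            "second_promoter_fraction": self.second_promoter_fraction,
            "weak_peak_fraction": self.weak_peak_fraction,
            "gc_background": self.gc_background,
            "gc_affected": self.gc_affected,
        }
        for name, v in fractions.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("coupling_r_control", "coupling_r_case", "coupling_r_negative"):
            if abs(getattr(self, name)) >= 1.0:
                raise ValueError(f"|{name}| must be < 1")
        lo, hi = self.composition_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("composition_range must be within [0, 1]")
        if self.global_shift <= 0 or self.nb_dispersion < 0:
            raise ValueError("global_shift must be > 0 and nb_dispersion >= 0")


@dataclass
class SyntheticTruth:
    """Ground-truth bookkeeping for one cohort; no silent effects."""

    affected_peaks: set = field(default_factory=set)
    affected_genes: set = field(default_factory=set)
    intergenic_affected_peaks: set = field(default_factory=set)
    true_composition: pd.DataFrame | None = None   # sample x cell type
    true_coupling: pd.DataFrame | None = None      # gene x (control, case)
    pd_gene_set: set = field(default_factory=set)
    negative_coupling_genes: set = field(default_factory=set)
    marker_sites: dict = field(default_factory=dict)  # cell type -> peak ids
    housekeeping_peaks: set = field(default_factory=set)


@dataclass
class Cohort:
    name: str
    peaks: pd.DataFrame
    counts: pd.DataFrame
    metadata: pd.DataFrame
    truth: SyntheticTruth
    annotations: pd.DataFrame


def _named_rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Independent deterministic stream per component (seed, stream key)."""
    key = int.from_bytes(stream.encode()[:4].ljust(4, b"_"), "big")
    return np.random.default_rng(np.random.SeedSequence([config.seed, key]))


def generate_gene_models(config: SimulationConfig,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Non-overlapping strand-aware gene models with long-tailed lengths.

    Each gene gets a TSS, a 5'UTR end, 1–8 exons, and flags for the
    housekeeping, disease-implicated and cell-type-marker subsets.
    """
    config.validate()
    rng = rng or _named_rng(config, "genes")
    n = config.n_genes
    lengths = np.minimum(
        config.min_gene_length * (1.0 + rng.pareto(config.gene_length_tail, size=n)),
        config.max_gene_length,
    ).astype(np.int64)
    margin = 10_000
    chrom_names = [f"chr{i + 1}" for i in range(len(config.genome_length))]
    chrom_len = np.asarray(config.genome_length, dtype=np.int64)
    # allocate genes to chromosomes proportionally to length, then place
    order = rng.permutation(n)
    quota = np.floor(n * chrom_len / chrom_len.sum()).astype(int)
    quota[-1] = n - quota[:-1].sum()
    rows = []
    idx = 0
    gi = 0
    for ci, cname in enumerate(chrom_names):
        take = order[idx: idx + quota[ci]]
        idx += quota[ci]
        ls = lengths[take]
        total = ls.sum() + 2 * margin
        if total > chrom_len[ci]:
            raise ValueError(
                f"{cname}: genome too small for {len(ls)} genes "
                f"({total} bp needed, {chrom_len[ci]} available)"
            )
        slack = chrom_len[ci] - total
        gaps = rng.dirichlet(np.ones(len(ls) + 1)) * slack
        cursor = margin
        for k, L in enumerate(ls):
            cursor += int(gaps[k])
            start, end = cursor, cursor + int(L)
            cursor = end
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            n_exons = int(rng.integers(1, 9))
            if n_exons == 1:
                exon_starts, exon_ends = [start], [end]
            else:
                cuts = np.sort(rng.choice(
                    np.arange(start + 50, end - 50), size=2 * (n_exons - 1),
                    replace=False,
                ))
                bounds = [start, *cuts.tolist(), end]
                exon_starts = bounds[0::2][:n_exons]
                exon_ends = bounds[1::2][:n_exons]
            first_len = (
                exon_ends[0] - exon_starts[0]
                if strand == "+"
                else exon_ends[-1] - exon_starts[-1]
            )
            utr_len = int(rng.integers(100, max(101, min(1000, first_len))))
            utr5_end = tss + utr_len if strand == "+" else tss - utr_len + 1
            rows.append(
                (
                    f"G{gi:05d}", f"GENE{gi:05d}", cname, start, end, strand,
                    tss, utr5_end, exon_starts, exon_ends,
                )
            )
            gi += 1
    genes = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "symbol", "chrom", "start", "end", "strand", "tss",
            "utr5_end", "exon_starts", "exon_ends",
        ],
    )
    genes["length"] = genes["end"] - genes["start"]
    genes["is_housekeeping"] = False
    genes["is_implicated"] = False
    genes["marker_type"] = ""
    # housekeeping: modest-length genes so a single saturated peak is realistic
    short = genes.sort_values("length").index[: max(3 * config.n_housekeeping, 10)]
    hk = rng.choice(short, size=config.n_housekeeping, replace=False)
    genes.loc[hk, "is_housekeeping"] = True
    free = genes.index.difference(hk)
    imp = rng.choice(free, size=config.n_implicated, replace=False)
    genes.loc[imp, "is_implicated"] = True
    free = free.difference(imp)
    for ct in CELL_TYPES:
        mk = rng.choice(free, size=config.n_marker_genes_per_type, replace=False)
        genes.loc[mk, "marker_type"] = ct
        free = free.difference(mk)
    return genes


def _generate_peaks(config: SimulationConfig, genes: pd.DataFrame,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Peak coordinates: saturated housekeeping peaks, marker-gene promoter
    peaks, one (sometimes two) promoter peak per gene, gene-body peaks and
    intergenic peaks, with lognormal widths (median ~800 bp)."""
    chrom_len = {f"chr{i + 1}": L for i, L in enumerate(config.genome_length)}
    rows = []  # chrom, start, end, kind, gene_id

    def clip(chrom, s, e):
        s = max(0, int(s))
        e = min(chrom_len[chrom], int(e))
        return s, e

    for g in genes[genes["is_housekeeping"]].itertuples():
        span = g.end - g.start
        s, e = clip(g.chrom, g.start + 0.02 * span, g.end - 0.02 * span)
        rows.append((g.chrom, s, e, "housekeeping", g.gene_id))
    for g in genes[genes["marker_type"] != ""].itertuples():
        s, e = clip(g.chrom, g.tss - 500, g.tss + 500)
        rows.append((g.chrom, s, e, f"marker_{g.marker_type}", g.gene_id))
    plain = genes[(genes["marker_type"] == "") & ~genes["is_housekeeping"]]
    for g in plain.itertuples():
        width = int(np.clip(rng.lognormal(np.log(800), 0.4), 200, 4000))
        s, e = clip(g.chrom, g.tss - width // 2, g.tss + width - width // 2)
        rows.append((g.chrom, s, e, "promoter", g.gene_id))
        if rng.random() < config.second_promoter_fraction:
            off = int(rng.integers(200, 800))
            if g.strand == "+":
                s2, e2 = clip(g.chrom, g.tss - 1000 - off, g.tss - off)
            else:
                s2, e2 = clip(g.chrom, g.tss + off, g.tss + 1000 + off)
            if e2 > s2:
                rows.append((g.chrom, s2, e2, "promoter2", g.gene_id))
    n_rest = max(0, config.n_peaks - len(rows))
    n_body = int(0.6 * n_rest)
    spans = genes[["chrom", "start", "end", "gene_id"]].to_numpy()
    weights = (genes["end"] - genes["start"]).to_numpy(float)
    weights /= weights.sum()
    picks = rng.choice(len(spans), size=n_body, p=weights)
    for gi in picks:
        chrom, gs, ge, gid = spans[gi]
        width = int(np.clip(rng.lognormal(np.log(800), 0.5), 200, 5000))
        pos = int(rng.integers(int(gs), int(ge)))
        s, e = clip(chrom, pos, pos + width)
        if e > s:
            rows.append((chrom, s, e, "body", gid))
    chroms = list(chrom_len)
    probs = np.array([chrom_len[c] for c in chroms], float)
    probs /= probs.sum()
    for _ in range(n_rest - n_body):
        c = chroms[rng.choice(len(chroms), p=probs)]
        width = int(np.clip(rng.lognormal(np.log(800), 0.5), 200, 5000))
        pos = int(rng.integers(0, chrom_len[c] - width))
        rows.append((c, pos, pos + width, "random", None))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "kind", "gene_id"])
    peaks = peaks.sort_values(["chrom", "start", "end"], kind="mergesort")
    peaks = peaks.reset_index(drop=True)
    peaks.insert(3, "peak_id", [f"Peak_{i:05d}" for i in range(len(peaks))])
    strong = 10.0 ** (-rng.uniform(8, 50, size=len(peaks)))
    weak = 10.0 ** (-rng.uniform(4, 6.5, size=len(peaks)))
    is_weak = rng.random(len(peaks)) < config.weak_peak_fraction
    is_weak &= ~peaks["kind"].isin(
        ["housekeeping", "marker_neuron", "marker_oligodendrocyte"]
    ).to_numpy()
    peaks["detection_p"] = np.where(is_weak, weak, strong)
    peaks["strand"] = "."
    return peaks


def _metadata(config: SimulationConfig, rng: np.random.Generator,
              prefix: str) -> pd.DataFrame:
    n = config.n_samples_per_group
    ids = [f"{prefix}_ctrl_{i:02d}" for i in range(n)] + [
        f"{prefix}_case_{i:02d}" for i in range(n)
    ]
    group = ["control"] * n + ["case"] * n
    meta = pd.DataFrame(
        {
            "sample_id": ids,
            "group": group,
            "age": np.round(rng.normal(72, 8, size=2 * n), 1),
            "sex": rng.choice(["F", "M"], size=2 * n),
            "pmi": np.round(rng.uniform(4, 30, size=2 * n), 1),
        }
    ).set_index("sample_id")
    if config.confound_batch_with_group:
        meta["batch"] = np.where(np.array(group) == "case", "b2", "b1")
    else:
        meta["batch"] = rng.permutation(
            np.array(["b1", "b2"]).repeat(n)
        )
    return meta


def _nb_sample(rng: np.random.Generator, mu: np.ndarray,
               alpha: np.ndarray) -> np.ndarray:
    """Gamma–Poisson draw: var = mu + alpha * mu^2 (Poisson when alpha=0)."""
    mu = np.clip(mu, 1e-12, None)
    a = np.broadcast_to(alpha, mu.shape)
    lam = np.where(
        a > 0,
        rng.gamma(np.clip(1.0 / np.where(a > 0, a, 1.0), 1e-12, None),
                  np.where(a > 0, a, 1.0) * mu),
        mu,
    )
    return rng.poisson(lam)


def generate_cohort(
    config: SimulationConfig,
    genes: pd.DataFrame,
    name: str = "A",
    affected_genes: set | None = None,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """One cohort: peaks, NB counts, metadata and the truth record.

    When ``affected_genes`` is given (replication cohort), affected peaks are
    drawn first from peaks annotated to those genes, topped up at random, so
    the two cohorts share truly affected genes.
    """
    config.validate()
    rng = rng or _named_rng(config, f"coh{name}")
    peaks = _generate_peaks(config, genes, rng)
    annotations = annotate_peaks(peaks, genes, scheme="structural")
    peak_gene = annotations.dropna(subset=["gene_id"]).groupby("peak_id")[
        "gene_id"
    ].agg(set)

    kind = peaks.set_index("peak_id")["kind"]
    protected = kind.isin(
        ["housekeeping", "marker_neuron", "marker_oligodendrocyte"]
    )
    eligible = kind.index[~protected]
    n_affected = int(round(config.shift_fraction * len(peaks)))
    n_affected = min(n_affected, len(eligible))
    if n_affected and affected_genes:
        on_gene = [
            pid for pid in eligible
            if peak_gene.get(pid, set()) & affected_genes
        ]
        take = list(rng.permutation(on_gene))[:n_affected]
        rest = [pid for pid in eligible if pid not in set(take)]
        extra = list(rng.permutation(rest))[: n_affected - len(take)]
        affected = sorted(take + extra)
    elif n_affected:
        affected = sorted(rng.choice(eligible, size=n_affected, replace=False))
    else:
        affected = []
    affected = set(affected)
    aff_genes = set().union(*(peak_gene.get(p, set()) for p in affected)) \
        if affected else set()
    intergenic_aff = {p for p in affected if not peak_gene.get(p, set())}

    meta = _metadata(config, rng, prefix=name)
    n_samples = len(meta)
    p_oligo = rng.uniform(*config.composition_range, size=n_samples)
    composition = pd.DataFrame(
        {"neuron": 1.0 - p_oligo, "oligodendrocyte": p_oligo}, index=meta.index
    )

    base_mu = np.exp(
        rng.normal(config.peak_mean_log_mu, config.peak_mean_log_sd, len(peaks))
    )
    alpha = np.full(len(peaks), config.nb_dispersion)
    kind_arr = peaks["kind"].to_numpy()
    hk_mask = kind_arr == "housekeeping"
    base_mu[hk_mask] = config.housekeeping_mean
    alpha[hk_mask] = config.housekeeping_dispersion
    marker_mu_floor = np.exp(config.peak_mean_log_mu)
    for ct in CELL_TYPES:
        m = kind_arr == f"marker_{ct}"
        base_mu[m] = np.maximum(base_mu[m], marker_mu_floor)

    lib = np.exp(rng.normal(0.0, config.libsize_log_sd, size=n_samples))
    mu = base_mu[:, None] * lib[None, :]
    for ct in CELL_TYPES:
        m = kind_arr == f"marker_{ct}"
        prop = composition[ct].to_numpy()
        mix = config.marker_contrast * prop + (1.0 - prop)
        mu[m] = mu[m] * mix[None, :]
    is_case = (meta["group"] == "case").to_numpy()
    aff_mask = peaks["peak_id"].isin(affected).to_numpy()
    shift = np.where(aff_mask[:, None] & is_case[None, :], config.global_shift, 1.0)
    mu = mu * shift
    counts = pd.DataFrame(
        _nb_sample(rng, mu, alpha[:, None]),
        index=peaks["peak_id"].to_numpy(),
        columns=meta.index,
    )

    truth = SyntheticTruth(
        affected_peaks=affected,
        affected_genes=aff_genes,
        intergenic_affected_peaks=intergenic_aff,
        true_composition=composition,
        pd_gene_set=set(genes.loc[genes["is_implicated"], "gene_id"]),
        marker_sites={
            ct: sorted(peaks.loc[kind_arr == f"marker_{ct}", "peak_id"])
            for ct in CELL_TYPES
        },
        housekeeping_peaks=set(peaks.loc[hk_mask, "peak_id"]),
    )
    return Cohort(name, peaks, counts, meta, truth, annotations)


def promoter_counts_by_gene(cohort: Cohort, genes: pd.DataFrame) -> pd.DataFrame:
    """Counts of each gene's designated (leftmost) promoter peak, indexed by
    gene id — the ChIP side of the coupling simulation."""
    pk = cohort.peaks
    prom = pk[pk["kind"].isin(["promoter", "promoter2", "marker_neuron",
                               "marker_oligodendrocyte"])]
    prom = prom.sort_values(["gene_id", "start"]).drop_duplicates("gene_id")
    mat = cohort.counts.loc[prom["peak_id"]]
    mat.index = prom["gene_id"].to_numpy()
    return mat.sort_index()


def generate_expression(
    config: SimulationConfig,
    genes: pd.DataFrame,
    promoter_counts: pd.DataFrame,
    groups: pd.Series,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression counts coupled to promoter acetylation via a Gaussian copula.

    Per gene and group, the latent log2 expression mean is
    ``r * z_promoter + sqrt(1-r^2) * noise`` where ``z_promoter`` is the
    within-group standardized log2(CPM+1) promoter signal and ``r`` the
    group's target coupling; NB sampling adds counting noise on top.
    Returns (expression counts, per-gene true coupling table).
    """
    config.validate()
    rng = rng or _named_rng(config, "expr")
    samples = promoter_counts.columns
    groups = groups.loc[samples]
    x = np.log2(
        promoter_counts.div(promoter_counts.sum(axis=0), axis=1) * 1e6 + 1.0
    ).to_numpy()
    z = np.zeros_like(x)
    for g in ("control", "case"):
        m = (groups == g).to_numpy()
        sub = x[:, m]
        sd = sub.std(axis=1)
        sd[sd == 0] = 1.0
        z[:, m] = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]

    gene_ids = promoter_counts.index.to_numpy()
    n_genes = len(gene_ids)
    r_ctrl = np.full(n_genes, config.coupling_r_control)
    r_case = np.full(n_genes, config.coupling_r_case)
    neg = set()
    if config.n_negative_coupling_genes:
        take = rng.choice(
            n_genes, size=min(config.n_negative_coupling_genes, n_genes),
            replace=False,
        )
        r_case[take] = config.coupling_r_negative
        neg = set(gene_ids[take])
    r = np.where(
        (groups == "case").to_numpy()[None, :], r_case[:, None], r_ctrl[:, None]
    )
    noise = rng.normal(size=z.shape)
    latent = r * z + np.sqrt(1.0 - r**2) * noise
    m_g = rng.normal(config.expression_mean_log2, config.expression_log2_sd,
                     size=n_genes)
    lib = np.exp(rng.normal(0.0, config.expression_libsize_log_sd,
                            size=len(samples)))
    mu = 2.0 ** (m_g[:, None] + config.latent_log2_sd * latent) * lib[None, :]
    expr = pd.DataFrame(
        _nb_sample(rng, mu, np.full((n_genes, 1), config.expression_dispersion)),
        index=gene_ids, columns=samples,
    )
    coupling = pd.DataFrame(
        {"r_control": r_ctrl, "r_case": r_case}, index=gene_ids
    )
    coupling["negative_coupling"] = coupling.index.isin(neg)
    return expr, coupling


def generate_binding_sites(
    config: SimulationConfig,
    peaks: pd.DataFrame,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Activator and deacetylase site tracks (sorted BED-like frames).

    Per-peak site counts are Poisson; the activator rate is multiplied by
    ``binding_enrichment`` (and the deacetylase rate divided by
    ``binding_deacetylase_depletion``) on truth-affected peaks.
    """
    rng = rng or _named_rng(config, "bind")
    aff = peaks["peak_id"].isin(truth.affected_peaks).to_numpy()
    rate_act = config.binding_rate_activator * np.where(
        aff, config.binding_enrichment, 1.0
    )
    rate_dea = config.binding_rate_deacetylase / np.where(
        aff, config.binding_deacetylase_depletion, 1.0
    )
    tracks = {}
    for factor, rates in (("activator", rate_act), ("deacetylase", rate_dea)):
        n_sites = rng.poisson(rates)
        rows = []
        for p, k in zip(peaks.itertuples(), n_sites):
            width = p.end - p.start
            for _ in range(int(k)):
                w = int(rng.integers(20, 120))
                s = p.start + int(rng.integers(0, max(1, width)))
                rows.append((p.chrom, s, min(s + w, p.end + w)))
        track = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        track["name"] = factor
        tracks[factor] = track.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)
    return tracks


def generate_sequences(
    config: SimulationConfig,
    peaks: pd.DataFrame,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Random peak sequences with class-specific GC content.

    Truth-affected peaks use ``gc_affected``, all others ``gc_background``;
    each sequence length equals its interval length.
    """
    rng = rng or _named_rng(config, "seqs")
    bases = np.array(list("ACGT"))
    out = {}
    aff = peaks["peak_id"].isin(truth.affected_peaks).to_numpy()
    for p, is_aff in zip(peaks.itertuples(), aff):
        gc = config.gc_affected if is_aff else config.gc_background
        probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        L = p.end - p.start
        out[p.peak_id] = "".join(bases[rng.choice(4, size=L, p=probs)])
    return out


def generate_reference_counts(
    config: SimulationConfig,
    peaks: pd.DataFrame,
    truth: SyntheticTruth,
    n_per_class: int = 4,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Sorted-cell (NeuN+/NeuN−) reference counts on the cohort peak-set.

    Marker sites are strongly class-specific (>4-fold, high mean) so the
    reference-DAR criteria recover them; everything else is class-neutral.
    """
    rng = rng or _named_rng(config, "refc")
    kind = peaks["kind"].to_numpy()
    ids = peaks["peak_id"].to_numpy()
    labels = ["NeuN+"] * n_per_class + ["NeuN-"] * n_per_class
    samples = [f"ref_pos_{i}" for i in range(n_per_class)] + [
        f"ref_neg_{i}" for i in range(n_per_class)
    ]
    mu = np.full((len(peaks), len(samples)), 300.0)
    pos = np.array([lab == "NeuN+" for lab in labels])
    mu[kind == "marker_neuron"] = np.where(pos, 4000.0, 150.0)
    mu[kind == "marker_oligodendrocyte"] = np.where(pos, 150.0, 4000.0)
    lib = np.exp(rng.normal(0.0, 0.2, size=len(samples)))
    counts = pd.DataFrame(
        _nb_sample(rng, mu * lib[None, :], np.full((len(peaks), 1), 0.02)),
        index=ids, columns=samples,
    )
    return counts, pd.Series(labels, index=samples, name="cell_class")


@dataclass
class Study:
    config: SimulationConfig
    genes: pd.DataFrame
    cohorts: dict[str, Cohort]
    expression: dict[str, pd.DataFrame]
    coupling: dict[str, pd.DataFrame]
    binding: dict[str, dict[str, pd.DataFrame]]
    reference_counts: pd.DataFrame
    reference_labels: pd.Series
    marker_genes: pd.DataFrame


def generate_study(config: SimulationConfig,
                   with_sequences: bool = False) -> Study:
    """The full two-cohort synthetic study.

    Cohort B's affected genes share ``shared_gene_fraction`` of cohort A's,
    mimicking partial cross-cohort replication of truly affected genes.
    """
    config.validate()
    genes = generate_gene_models(config)
    coh_a = generate_cohort(config, genes, name="A")
    rng = _named_rng(config, "share")
    aff_a = sorted(coh_a.truth.affected_genes)
    n_share = int(round(config.shared_gene_fraction * len(aff_a)))
    shared = set(rng.choice(aff_a, size=n_share, replace=False)) if n_share else set()
    coh_b = generate_cohort(config, genes, name="B", affected_genes=shared)
    expression, coupling, binding = {}, {}, {}
    for name, coh in (("A", coh_a), ("B", coh_b)):
        prom = promoter_counts_by_gene(coh, genes)
        expr, coup = generate_expression(
            config, genes, prom, coh.metadata["group"],
            rng=_named_rng(config, f"exp{name}"),
        )
        coh.truth.true_coupling = coup
        coh.truth.negative_coupling_genes = set(
            coup.index[coup["negative_coupling"]]
        )
        expression[name] = expr
        coupling[name] = coup
        binding[name] = generate_binding_sites(
            config, coh.peaks, coh.truth, rng=_named_rng(config, f"bnd{name}")
        )
    ref_counts, ref_labels = generate_reference_counts(
        config, coh_a.peaks, coh_a.truth
    )
    marker_genes = genes.loc[
        genes["marker_type"] != "", ["marker_type", "symbol", "gene_id"]
    ].rename(columns={"marker_type": "cell_type"}).reset_index(drop=True)
    study = Study(
        config=config, genes=genes, cohorts={"A": coh_a, "B": coh_b},
        expression=expression, coupling=coupling, binding=binding,
        reference_counts=ref_counts, reference_labels=ref_labels,
        marker_genes=marker_genes,
    )
    return study


def write_study(study: Study, outdir) -> None:
    """Write every table of the study as deterministic plain text."""
    import pathlib

    import yaml

    from . import io as asio

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    asio.write_gene_table(study.genes.assign(), out / "genes.tsv")
    study.marker_genes.to_csv(out / "marker_genes.tsv", sep="\t", index=False)
    asio.write_counts(study.reference_counts, out / "reference_counts.tsv")
    study.reference_labels.to_frame().to_csv(out / "reference_labels.tsv", sep="\t")
    summary = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in asdict(study.config).items()}}
    for name, coh in study.cohorts.items():
        asio.peaks_to_bed(coh.peaks, out / f"cohort{name}_peaks.bed")
        asio.write_counts(coh.counts, out / f"cohort{name}_counts.tsv")
        coh.metadata.to_csv(out / f"cohort{name}_metadata.tsv", sep="\t")
        asio.write_counts(study.expression[name], out / f"cohort{name}_expression.tsv")
        for factor, track in study.binding[name].items():
            asio.write_bed(track, out / f"cohort{name}_sites_{factor}.bed")
        truth = coh.truth
        pd.DataFrame(
            {"peak_id": sorted(truth.affected_peaks)}
        ).assign(
            intergenic=lambda d: d["peak_id"].isin(truth.intergenic_affected_peaks)
        ).to_csv(out / f"cohort{name}_truth_affected_peaks.tsv", sep="\t", index=False)
        truth.true_composition.to_csv(
            out / f"cohort{name}_truth_composition.tsv", sep="\t"
        )
        truth.true_coupling.to_csv(out / f"cohort{name}_truth_coupling.tsv", sep="\t")
        summary[f"cohort{name}"] = {
            "n_peaks": int(len(coh.peaks)),
            "n_affected_peaks": len(truth.affected_peaks),
            "n_affected_genes": len(truth.affected_genes),
            "n_intergenic_affected": len(truth.intergenic_affected_peaks),
            "housekeeping_peaks": sorted(truth.housekeeping_peaks),
        }
    with open(out / "truth_summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
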