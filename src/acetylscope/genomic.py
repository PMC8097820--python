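"""Interval algebra, peak filtering, peak-to-gene annotation and peak-set
comparison.

Coordinates are 0-based half-open throughout.  The overlap predicate is
">= 1 bp" everywhere.  Gene models are strand-aware: on the + strand the TSS
is the gene start and the 5'UTR runs rightward to ``utr5_end``; on the −
strand the TSS is ``end - 1`` and the 5'UTR runs leftward down to
``utr5_end``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

STRUCTURAL_CATEGORIES = ("promoter", "1to5kb", "5UTR", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __len__(self) -> int:
        return self.end - self.start


def _trees_from_frame(df: pd.DataFrame, payload=None) -> dict:
    trees: dict[str, IntervalTree] = {}
    payloads = payload if payload is not None else df.index
    for chrom, s, e, data in zip(df["chrom"], df["start"], df["end"], payloads):
        trees.setdefault(chrom, IntervalTree()).addi(int(s), int(e), data)
    return trees


def validate_genes(genes: pd.DataFrame) -> None:
    """Check the GeneModel invariants (TSS position, exons inside span)."""
    for g in genes.itertuples():
        expected_tss = g.start if g.strand == "+" else g.end - 1
        if g.tss != expected_tss:
            raise ValueError(f"{g.gene_id}: tss {g.tss} != expected {expected_tss}")
        for es, ee in zip(g.exon_starts, g.exon_ends):
            if not (g.start <= es < ee <= g.end):
                raise ValueError(f"{g.gene_id}: exon [{es},{ee}) outside span")


def gene_windows(gene, scheme: str, promoter_bp: int = 1000,
                 upstream_bp: int = 5000) -> list[tuple[int, int, str]]:
    """Category windows for one gene row, clipped at the chromosome start.

    ``msp_window``: the single span from ``upstream_bp`` upstream of the TSS
    to the end of the 5'UTR (strand-adjusted).  ``structural``: promoter,
    1to5kb, 5UTR, exon and intron windows.
    """
    tss, strand = int(gene.tss), gene.strand
    out: list[tuple[int, int, str]] = []
    if strand == "+":
        if scheme == "msp_window":
            out.append((max(0, tss - upstream_bp), int(gene.utr5_end), "msp_window"))
        else:
            out.append((max(0, tss - promoter_bp), tss, "promoter"))
            out.append((max(0, tss - upstream_bp), max(0, tss - promoter_bp), "1to5kb"))
            out.append((tss, int(gene.utr5_end), "5UTR"))
    else:
        if scheme == "msp_window":
            out.append((int(gene.utr5_end), tss + 1 + upstream_bp, "msp_window"))
        else:
            out.append((tss + 1, tss + 1 + promoter_bp, "promoter"))
            out.append((tss + 1 + promoter_bp, tss + 1 + upstream_bp, "1to5kb"))
            out.append((int(gene.utr5_end), tss + 1, "5UTR"))
    if scheme == "structural":
        exons = sorted(zip(gene.exon_starts, gene.exon_ends))
        for es, ee in exons:
            out.append((int(es), int(ee), "exon"))
        cursor = int(gene.start)
        for es, ee in exons:
            if es > cursor:
                out.append((cursor, int(es), "intron"))
            cursor = max(cursor, int(ee))
        if cursor < gene.end:
            out.append((cursor, int(gene.end), "intron"))
    return [(s, e, c) for s, e, c in out if s < e]


def annotate_peaks(peaks: pd.DataFrame, genes: pd.DataFrame, scheme: str = "structural",
                   promoter_bp: int = 1000, upstream_bp: int = 5000) -> pd.DataFrame:
    """Assign peaks to gene categories by >=1 bp interval overlap.

    ``structural`` emits one record per intersecting (peak, gene, category)
    triple and an ``intergenic`` record (gene_id = NA) for peaks that hit no
    gene window.  ``msp_window`` emits (peak, gene, 'msp_window') records
    only.  Output is sorted, hence independent of input ordering.
    """
    if scheme not in {"structural", "msp_window"}:
        raise ValueError(f"unknown scheme {scheme!r}")
    trees: dict[str, IntervalTree] = {}
    for gene in genes.itertuples():
        for s, e, cat in gene_windows(gene, scheme, promoter_bp, upstream_bp):
            trees.setdefault(gene.chrom, IntervalTree()).addi(s, e, (gene.gene_id, cat))
    records = []
    for p in peaks.itertuples():
        hits = trees.get(p.chrom, IntervalTree()).overlap(p.start, p.end)
        seen = {iv.data for iv in hits}
        if not seen and scheme == "structural":
            records.append((p.peak_id, None, "intergenic"))
        for gene_id, cat in seen:
            records.append((p.peak_id, gene_id, cat))
    out = pd.DataFrame(records, columns=["peak_id", "gene_id", "category"])
    return out.sort_values(
        ["peak_id", "gene_id", "category"], na_position="last"
    ).reset_index(drop=True)


def filter_peaks(peaks: pd.DataFrame, blacklist: pd.DataFrame | None = None,
                 canonical_chroms: set | None = None,
                 max_detection_p: float = 1e-7) -> pd.DataFrame:
    """Drop blacklisted, non-canonical and weakly detected peaks.

    A peak is removed if it overlaps any blacklist interval by >=1 bp, lies
    on a chromosome outside ``canonical_chroms``, or has detection p-value
    above ``max_detection_p``.  Idempotent.
    """
    keep = np.ones(len(peaks), dtype=bool)
    if canonical_chroms is not None:
        keep &= peaks["chrom"].isin(canonical_chroms).to_numpy()
    if max_detection_p is not None:
        keep &= peaks["detection_p"].to_numpy(float) <= max_detection_p
    if blacklist is not None and len(blacklist):
        trees = _trees_from_frame(blacklist)
        hit = np.array(
            [
                bool(trees.get(p.chrom, IntervalTree()).overlap(p.start, p.end))
                for p in peaks.itertuples()
            ]
        )
        keep &= ~hit
    return peaks.loc[keep].reset_index(drop=True)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union footprint of a set of intervals, per chromosome."""
    merged = []
    for chrom, grp in df.groupby("chrom", sort=True):
        spans = sorted(zip(grp["start"], grp["end"]))
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])


def footprint_bp(df: pd.DataFrame) -> int:
    if len(df) == 0:
        return 0
    m = merge_intervals(df)
    return int((m["end"] - m["start"]).sum())


def peakset_comparison(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame,
                       genome_size: int) -> dict:
    """Compare two peak-sets: size, % unique peaks, % genome covered.

    A peak is "unique" when it overlaps no peak of the other set by >=1 bp.
    Coverage is the merged footprint as a percentage of ``genome_size``.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")

    def _summary(this: pd.DataFrame, other: pd.DataFrame) -> dict:
        trees = _trees_from_frame(other)
        unique = sum(
            not trees.get(p.chrom, IntervalTree()).overlap(p.start, p.end)
            for p in this.itertuples()
        )
        return {
            "n_peaks": int(len(this)),
            "percent_unique": 100.0 * unique / len(this) if len(this) else 0.0,
            "percent_coverage": 100.0 * footprint_bp(this) / genome_size,
        }

    return {"A": _summary(peaks_a, peaks_b), "B": _summary(peaks_b, peaks_a)}


def gc_content(sequence: str) -> float:
    """Fraction (G+C)/(A+C+G+T); N bases excluded.  NaN when undefined."""
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return float("nan")
    return (counts["G"] + counts["C"]) / denom


def effective_gene_length(genes: pd.DataFrame, upstream_bp: int = 1000) -> pd.Series:
    """Effective gene length: gene span plus 1 kb upstream of the TSS.

    Used as the length covariate in the gene-length regression; the upstream
    kilobase is included because promoter windows are annotated to the gene.
    """
    span = genes["end"].to_numpy() - genes["start"].to_numpy()
    upstream = np.where(
        genes["strand"] == "+",
        np.minimum(genes["start"].to_numpy(), upstream_bp),
        upstream_bp,
    )
    return pd.Series(span + upstream, index=genes["gene_id"], name="egl")
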