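"""Readers and writers for the plain-text formats used across the pipeline.

All genomic coordinates are 0-based half-open (BED convention) both on disk
and in memory.  Peaks travel as BED6+1: the score column holds
-log10(detection p) for browser display and the seventh column holds the
detection p-value at full precision so that read/write round-trips exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

GENE_TABLE_COLUMNS = [
    "gene_id", "symbol", "chrom", "start", "end", "strand", "tss",
    "utr5_end", "exon_starts", "exon_ends", "is_housekeeping", "is_implicated",
]


class BedParseError(ValueError):
    """Malformed BED line; carries the 1-based line number."""


def read_bed(path) -> pd.DataFrame:
    """Read a BED3/BED6+ file into a DataFrame.

    Extra columns beyond the canonical six are kept as ``extra_<i>`` strings.
    Raises :class:`BedParseError` (with line number) on malformed records,
    including empty intervals (start >= end).
    """
    rows = []
    n_extra = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
            if not fields[0]:
                raise BedParseError(f"line {lineno}: empty chromosome name")
            if start < 0 or start >= end:
                raise BedParseError(
                    f"line {lineno}: invalid interval [{start}, {end})"
                )
            row = [fields[0], start, end]
            row.append(fields[3] if len(fields) > 3 else ".")
            row.append(float(fields[4]) if len(fields) > 4 else 0.0)
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in {"+", "-", "."}:
                raise BedParseError(f"line {lineno}: bad strand {strand!r}")
            row.append(strand)
            extras = fields[6:]
            n_extra = max(n_extra, len(extras))
            rows.append(row + extras)
    columns = BED_COLUMNS + [f"extra_{i}" for i in range(n_extra)]
    out = pd.DataFrame(
        [r + ["."] * (len(columns) - len(r)) for r in rows], columns=columns
    )
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    return out


def write_bed(df: pd.DataFrame, path) -> None:
    """Write a BED6+ DataFrame (columns beyond the canonical six appended)."""
    cols = [c for c in BED_COLUMNS if c in df.columns]
    extras = [c for c in df.columns if c not in BED_COLUMNS]
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            fields = []
            for c in cols + extras:
                v = row[c]
                if isinstance(v, float):
                    fields.append(f"{v:.17g}")
                else:
                    fields.append(str(v))
            fh.write("\t".join(fields) + "\n")


def peaks_to_bed(peaks: pd.DataFrame, path) -> None:
    """Write a peak table (chrom/start/end/peak_id/detection_p[/strand])."""
    df = peaks.copy()
    bed = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": df["peak_id"],
            "score": -np.log10(df["detection_p"].to_numpy(float)),
            "strand": df.get("strand", pd.Series(["."] * len(df))).fillna("."),
            "detection_p": df["detection_p"],
        }
    )
    write_bed(bed, path)


def bed_to_peaks(path) -> pd.DataFrame:
    """Read a peak BED written by :func:`peaks_to_bed` (or any BED6+).

    Detection p is taken from the seventh column when present, otherwise
    reconstructed from the score column as ``10**-score``.
    """
    bed = read_bed(path)
    if "extra_0" in bed.columns:
        detection_p = bed["extra_0"].astype(float)
    else:
        detection_p = 10.0 ** (-bed["score"].astype(float))
    peaks = pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "start": bed["start"],
            "end": bed["end"],
            "peak_id": bed["name"],
            "detection_p": detection_p,
            "strand": bed["strand"],
        }
    )
    if peaks["peak_id"].duplicated().any():
        dup = peaks.loc[peaks["peak_id"].duplicated(), "peak_id"].iloc[0]
        raise BedParseError(f"duplicate peak id {dup!r}")
    return peaks


def write_gene_table(genes: pd.DataFrame, path) -> None:
    df = genes.copy()
    for col in ("exon_starts", "exon_ends"):
        df[col] = df[col].map(
            lambda v: ",".join(str(int(x)) for x in v) if not isinstance(v, str) else v
        )
    df[GENE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"exon_starts": str, "exon_ends": str}
    )
    for col in ("exon_starts", "exon_ends"):
        df[col] = df[col].map(lambda s: [int(x) for x in str(s).split(",")])
    for col in ("is_housekeeping", "is_implicated"):
        df[col] = df[col].astype(bool)
    return df


def write_fasta(sequences: dict, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")
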