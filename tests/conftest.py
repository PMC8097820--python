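import numpy as np
import pandas as pd
import pytest

from acetylscope import simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(
        n_peaks=800,
        n_genes=250,
        n_samples_per_group=6,
        n_implicated=20,
        n_marker_genes_per_type=10,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate.generate_study(small_config)


@pytest.fixture(scope="session")
def small_genes(small_study):
    return small_study.genes


def make_genes(rows):
    """Gene table from (gene_id, chrom, start, end, strand, tss, utr5_end,
    exon_starts, exon_ends) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "start", "end", "strand", "tss", "utr5_end",
            "exon_starts", "exon_ends",
        ],
    )
    df["symbol"] = df["gene_id"]
    df["is_housekeeping"] = False
    df["is_implicated"] = False
    return df


def make_peaks(rows):
    """Peak table from (peak_id, chrom, start, end) tuples."""
    df = pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end"])
    df["detection_p"] = 1e-10
    df["strand"] = "."
    return df[["chrom", "start", "end", "peak_id", "detection_p", "strand"]]


def rng(seed=0):
    return np.random.default_rng(seed)
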