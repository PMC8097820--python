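#!/usr/bin/env python
"""Compare the two cohorts' peak-sets: peak counts, group-unique fractions
and genome coverage — the coarse signature of a genome-wide occupancy
difference."""

import pathlib
import sys

import pandas as pd

from acetylscope import genomic, pipeline, simulate

OUT = pathlib.Path("results")


def main():
    cfg = pipeline.default_study_config()
    study = simulate.generate_study(cfg)
    canonical = {f"chr{i + 1}" for i in range(len(cfg.genome_length))}
    peaks = {
        name: genomic.filter_peaks(coh.peaks, canonical_chroms=canonical)
        for name, coh in study.cohorts.items()
    }
    cmp = genomic.peakset_comparison(
        peaks["A"], peaks["B"], genome_size=int(sum(cfg.genome_length))
    )
    table = pd.DataFrame(cmp).T.reset_index(names="cohort")
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "peakset_comparison.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print("\nBoth synthetic cohorts share the peak architecture, so unique "
          "fractions and coverage are symmetric here; in real data a "
          "hyperacetylated group shows more peaks, more unique peaks and "
          "wider coverage.")
    return 0


if __name__ == "__main__":
    sys.exit(main())
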