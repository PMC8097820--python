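#!/usr/bin/env python
"""Derive cell-type marker sites from the sorted-nuclei reference and compute
per-sample Marker Site Profiles (MSPs); validate against the simulated true
cell composition."""

import pathlib
import sys

import numpy as np

from acetylscope import pipeline, simulate

OUT = pathlib.Path("results")


def main():
    cfg = pipeline.default_study_config()
    study = simulate.generate_study(cfg)
    OUT.mkdir(exist_ok=True)
    for name, coh in study.cohorts.items():
        msp = pipeline.cohort_msp(study, coh)
        msp.to_csv(OUT / f"msp_cohort{name}.tsv", sep="\t")
        truth = coh.truth.true_composition["oligodendrocyte"]
        r = np.corrcoef(msp["oligodendrocyte"], truth.loc[msp.index])[0, 1]
        print(f"cohort {name}: MSP vs true oligodendrocyte proportion "
              f"Pearson r = {r:.3f} over {len(msp)} samples")
    print("\nMSP scores recover the simulated cell composition; the "
          "oligodendrocyte MSP is carried forward as a covariate in the "
          "differential stage.")
    return 0


if __name__ == "__main__":
    sys.exit(main())
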