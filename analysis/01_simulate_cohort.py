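#!/usr/bin/env python
"""Generate a demonstration synthetic cohort and save its ground truth.

Writes the covariate table, the per-patient per-tissue truth (target
enhancement slopes, Ktrans, T10, MD, FA) and one example patient's image
volumes, so later steps and readers can inspect exactly what the generator
produces.
"""

from pathlib import Path

import numpy as np

from bbbflow import io as bio
from bbbflow.config import CohortConfig
from bbbflow.synthetic import generate_cohort, simulate_cognition, \
    simulate_dce, simulate_dwi
from bbbflow.synthetic.anatomy import generate_anatomy
from bbbflow.synthetic.dwi import default_gradient_scheme

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
#: example volumes are bulky binaries; they go to scratch, tables to results
VOLS = Path(__file__).resolve().parents[1] / "scratch" / "cohort_volumes"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    VOLS.mkdir(parents=True, exist_ok=True)
    config = CohortConfig(n_patients=30, seed=20)
    cohort = generate_cohort(config)
    cov = simulate_cognition(cohort)
    bio.write_table(OUT / "covariates.csv", cov)
    bio.write_table(OUT / "tissue_truth.csv", cohort.truth.table)
    config.to_yaml(OUT / "config.yaml")

    # one example patient's raw volumes
    pid = int(cov.loc[cov.fazekas_score.idxmax(), "patient_id"])
    rng = np.random.default_rng([config.seed, pid])
    anatomy = generate_anatomy(config, int(cov.fazekas_score.max()),
                               rng=rng)
    labels = anatomy.truth_labels(config.n_contours,
                                  config.contour_width_voxels)
    dce, pre = simulate_dce(labels, cohort.patient_params(pid), config, rng)
    bvals, bvecs = default_gradient_scheme()
    dwi = simulate_dwi(labels, cohort.patient_params(pid), bvals, bvecs)
    for name, vol in [("dce", dce.data), ("pre_low", pre.low_flip),
                      ("pre_high", pre.high_flip), ("dwi", dwi),
                      ("labels", labels), ("flair", anatomy.flair)]:
        bio.write_volume(VOLS / f"example_{name}.nii",
                         np.asarray(vol, np.float32))
    bio.write_bvals_bvecs(VOLS / "example_dwi", bvals, bvecs)

    print(f"cohort tables in {OUT}; example volumes in {VOLS}")
    print(cov[["age_years", "fazekas_score", "stroke_subtype",
               "acer_baseline", "acer_1yr"]].describe().round(2))


if __name__ == "__main__":
    main()
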