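"""Parameter-recovery and calibration experiments.

These run the whole region-resolution loop — generate a cohort at stated
effect sizes, measure slopes with the package's estimator, fit the models —
and score whether the fitted 95% confidence intervals cover the generating
truth.  They are used both by the test suite and by the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CohortConfig
from .stats import (ModelSpec, fit_cognition_model, fit_contour_gradient,
                    fit_leakage_model)
from .synthetic import generate_cohort, simulate_cognition, \
    simulate_region_slopes
from .synthetic.truth import CovariateEffects


def _rep_seeds(seed: int, n_reps: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, n_reps)


def cognition_frame(cohort, table) -> pd.DataFrame:
    """Per-patient frame for the cognition models: ACE-R scores plus the
    *observed* WMH leakage slope."""
    cov = simulate_cognition(cohort)
    wmh_obs = (table[table.tissue == "wmh"][["patient_id", "slope_1e3"]]
               .rename(columns={"slope_1e3": "wmh_slope_1e3"}))
    return cov.merge(wmh_obs, on="patient_id", how="left")


def one_replicate(n_patients: int, seed: int,
                  effects: CovariateEffects | None = None,
                  config_kwargs: dict | None = None) -> dict:
    """Generate one cohort and fit the three headline models.

    Returns estimates, CI bounds and coverage indicators for: the NAWM
    Fazekas effect, the per-contour leakage gradient, and the pooled
    leakage-on-ACE-R-change effect.
    """
    effects = CovariateEffects.reference() if effects is None else effects
    kwargs = dict(n_patients=n_patients, seed=int(seed))
    if config_kwargs:
        kwargs.update(config_kwargs)
    config = CohortConfig(**kwargs)
    cohort = generate_cohort(config, effects)
    table = simulate_region_slopes(cohort)

    out: dict = {"seed": int(seed)}

    faz = fit_leakage_model(table, ModelSpec(covariate="fazekas_score"))
    row = faz[faz.tissue == "nawm"].iloc[0]
    truth = effects.beta_fazekas["nawm"]
    out.update(faz_nawm_est=row.estimate, faz_nawm_lo=row.ci95_low,
               faz_nawm_hi=row.ci95_high, faz_nawm_truth=truth,
               faz_nawm_covered=bool(row.ci95_low <= truth <= row.ci95_high))

    grad = fit_contour_gradient(table, n_contours=config.n_contours).iloc[0]
    gt = effects.contour_gradient_1e3
    out.update(gradient_est=grad.estimate, gradient_lo=grad.ci95_low,
               gradient_hi=grad.ci95_high, gradient_truth=gt,
               gradient_covered=bool(grad.ci95_low <= gt <= grad.ci95_high))

    # parameter recovery refits the generating model, so the leakage
    # exposure is the generator's own (true-slope) WMH leakage; the
    # observed-slope variant is the pipeline's realistic model
    cog = fit_cognition_model(cognition_frame(cohort, table),
                              include_baseline_acer=True,
                              leak_col="wmh_true_slope_1e3").iloc[0]
    # pooled change-model truth is the common subtype coefficient
    ct = 0.5 * (effects.beta_leak_lacunar + effects.beta_leak_cortical)
    out.update(acer_est=cog.estimate, acer_lo=cog.ci95_low,
               acer_hi=cog.ci95_high, acer_truth=ct,
               acer_covered=bool(cog.ci95_low <= ct <= cog.ci95_high))
    return out


def recovery_experiment(n_reps: int = 100, n_patients: int = 200,
                        seed: int = 0,
                        effects: CovariateEffects | None = None,
                        config_kwargs: dict | None = None) -> pd.DataFrame:
    """Replicate cohorts at the stated effect sizes; one row per replicate."""
    rows = [one_replicate(n_patients, s, effects, config_kwargs)
            for s in _rep_seeds(seed, n_reps)]
    return pd.DataFrame(rows)


def coverage_summary(reps: pd.DataFrame) -> dict:
    """Fraction of replicates whose 95% CI covered the truth, per target."""
    return {name: float(reps[f"{name}_covered"].mean())
            for name in ("faz_nawm", "gradient", "acer")}


def null_type1_experiment(n_reps: int = 400, n_patients: int = 100,
                          seed: int = 0,
                          tissues=("nawm", "dgm", "wmh")) -> pd.DataFrame:
    """Type-I error of the per-tissue Fazekas test under a null generator."""
    effects = CovariateEffects.null()
    rows = []
    for s in _rep_seeds(seed, n_reps):
        config = CohortConfig(n_patients=n_patients, seed=int(s))
        cohort = generate_cohort(config, effects)
        table = simulate_region_slopes(cohort)
        faz = fit_leakage_model(
            table, ModelSpec(covariate="fazekas_score", tissues=tissues))
        for r in faz.itertuples():
            rows.append({"seed": int(s), "tissue": r.tissue,
                         "estimate": r.estimate, "p_value": r.p_value,
                         "reject_05": bool(r.p_value < 0.05)})
    return pd.DataFrame(rows)
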