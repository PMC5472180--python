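"""Cohort-level generation: covariates, per-patient tissue truth, region
enhancement curves, and cognition.

Two resolutions share one forward model:

* the **region mode** evaluates each homogeneous compartment once per
  patient (the region mean of a homogeneous compartment equals its
  single-voxel evaluation) and adds noise to the region-mean curve — this is
  the resolution at which parameter-recovery experiments run;
* the **image mode** (``generate_anatomy`` + ``simulate_dce`` /
  ``simulate_dwi``) rasterises the same truth voxelwise for end-to-end
  pipeline runs.

Covariate effects act on the enhancement-slope scale (x 1e-3 per minute);
per-patient Ktrans is derived by inverting the forward model's affine
slope calibration.  Patients with Fazekas 0 carry no WMH and therefore no
WMH or contour rows, as in a real cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..config import CohortConfig, ConfigError
from ..dce import REPORT_SCALE, ols_slopes, vif_level, EnhancementSeries
from . import truth as T
from .forward import cp_plasma, enhancement_curve, solve_ktrans_for_slope
from .truth import CovariateEffects, TissueParams

log = logging.getLogger(__name__)

#: generative cognition coefficients besides the leakage effects
COGNITION_PARAMS = {
    "base_intercept": 55.0, "base_per_nart": 0.35, "base_per_age5": -0.6,
    "base_noise_sd": 3.0,
    "oneyr_intercept": 5.0, "oneyr_per_base": 0.8, "oneyr_per_nart": 0.05,
    "oneyr_noise_sd": 3.0,
}


@dataclass
class CohortTruth:
    """Everything needed to check recovery: the generating effects, the
    per-patient per-tissue truth table, and the cognition coefficients."""

    effects: CovariateEffects
    table: pd.DataFrame          # patient_id, tissue, true_slope_1e3, ...
    patient_intercepts_1e3: np.ndarray
    cognition: dict = field(default_factory=lambda: dict(COGNITION_PARAMS))
    n_ktrans_clipped: int = 0


@dataclass
class Cohort:
    config: CohortConfig
    covariates: pd.DataFrame
    truth: CohortTruth

    def patient_params(self, patient_id: int) -> dict[str, TissueParams]:
        """Per-compartment :class:`TissueParams` for image-mode simulation."""
        sub = self.truth.table[self.truth.table.patient_id == patient_id]
        out = {}
        for row in sub.itertuples():
            out[row.tissue] = TissueParams(
                t10_ms=row.t10_ms, m0=row.m0,
                ktrans_per_min=row.ktrans_per_min, vp=row.vp,
                md_true=row.md_true, fa_true=row.fa_true)
        faz = float(self.covariates.set_index("patient_id")
                    .loc[patient_id, "fazekas_score"])
        out["sinus"] = T.base_tissue_params("sinus", faz)
        return out


def _draw_covariates(config: CohortConfig, effects: CovariateEffects,
                     rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    age = rng.uniform(34.0, 97.0, n)
    faz = np.clip(np.rint(rng.normal(2.0, 1.5, n)), 0, 6).astype(int)
    lacunar = (rng.random(n) < 0.46).astype(int)
    htn = (rng.random(n) < 0.65).astype(int)
    map_mmhg = rng.normal(100.0, 12.0, n)
    pp = rng.normal(55.0, 12.0, n)
    smoker = (rng.random(n) < 0.30).astype(int)
    nart = np.clip(rng.normal(110.0, 8.0, n), 80.0, 130.0)
    old = (rng.random(n) < 0.35).astype(int)
    df = pd.DataFrame({
        "patient_id": np.arange(n),
        "age_years": age,
        "age5": (age - 65.0) / 5.0,
        "fazekas_score": faz,
        "stroke_subtype": np.where(lacunar == 1, "lacunar", "cortical"),
        "lacunar": lacunar,
        "hypertension": htn,
        "map_mmHg": map_mmhg,
        "map_c": map_mmhg - 100.0,
        "pulse_pressure_mmHg": pp,
        "pp_c": pp - 55.0,
        "smoker": smoker,
        "nart": nart,
        "has_old_infarct": old,
    })
    return df


def generate_cohort(config: CohortConfig,
                    effects: CovariateEffects | None = None,
                    rng: np.random.Generator | None = None) -> Cohort:
    """Draw covariates and per-patient per-tissue ground truth.

    True slopes are ``base(tissue) + patient intercept + linear covariate
    effects``; Ktrans is derived from the target slope through the forward
    model's affine calibration at the patient's tissue T10 (clipped at zero
    — leakage cannot be negative — with a count recorded on the truth).
    """
    if config.n_patients < 2:
        raise ConfigError("n_patients: need at least 2 patients")
    effects = CovariateEffects.reference() if effects is None else effects
    rng = np.random.default_rng(config.seed) if rng is None else rng

    cov = _draw_covariates(config, effects, rng)
    u = rng.normal(0.0, config.patient_slope_sd_1e3, config.n_patients)
    t10_sd = 20.0   # independent inter-subject T1 variability, ms

    vocab = [t for t in T.tissue_vocabulary(config.n_contours)
             if t != "sinus"]
    rows = []
    for i, c in enumerate(cov.itertuples()):
        for tissue in vocab:
            wm_dependent = (tissue.startswith("contour_")
                            or tissue.startswith("wmh"))
            if c.fazekas_score == 0 and wm_dependent:
                continue   # no visible WMH: no WMH or penumbra compartments
            if tissue == "old_infarct" and not c.has_old_infarct:
                continue
            s = (T.base_slope_1e3(tissue, effects.contour_gradient_1e3)
                 + u[i]
                 + effects.slope_effect(
                     tissue, age5=c.age5, fazekas=c.fazekas_score,
                     lacunar=c.lacunar, hypertension=c.hypertension,
                     map_c=c.map_c, pp_c=c.pp_c, smoker=c.smoker))
            p = T.base_tissue_params(tissue, c.fazekas_score)
            rows.append({
                "patient_id": c.patient_id, "tissue": tissue,
                "true_slope_1e3": s,
                "t10_ms": p.t10_ms + rng.normal(0.0, t10_sd),
                "m0": p.m0,
                "vp": p.vp, "md_true": p.md_true, "fa_true": p.fa_true,
            })
    table = pd.DataFrame(rows)

    ktrans, n_clip = solve_ktrans_for_slope(
        table.true_slope_1e3.to_numpy() / REPORT_SCALE,
        table.vp.to_numpy(), table.t10_ms.to_numpy(), config)
    if n_clip:
        log.info("generate_cohort: %d/%d negative target Ktrans clipped to 0",
                 n_clip, len(table))
    table["ktrans_per_min"] = ktrans

    truth = CohortTruth(effects=effects, table=table,
                        patient_intercepts_1e3=u, n_ktrans_clipped=n_clip)
    return Cohort(config=config, covariates=cov, truth=truth)


def simulate_region_slopes(cohort: Cohort,
                           rng: np.random.Generator | None = None,
                           noise_sd: float | None = None,
                           return_curves: bool = False):
    """Measure per-tissue enhancement slopes at region resolution.

    Evaluates the forward model for every (patient, tissue) row of the truth
    table, adds Gaussian noise of sd ``noise_sd`` (default: the config's
    ``region_noise_sd``) to the region-mean enhancement, and estimates
    slopes with the package's OLS estimator.  Returns the long slope table;
    with ``return_curves`` also the frame-level enhancement table used by
    the direct longitudinal models.
    """
    config = cohort.config
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    sd = config.region_noise_sd if noise_sd is None else noise_sd
    tab = cohort.truth.table
    times = config.times_min

    enh = enhancement_curve(tab.ktrans_per_min.to_numpy(),
                            tab.vp.to_numpy(), tab.t10_ms.to_numpy(), config)
    if sd > 0:
        enh = enh + rng.normal(0.0, sd, enh.shape)
    slopes = ols_slopes(times, enh)

    # blood-pool reference per patient (T10 jitter gives it some variance)
    n = config.n_patients
    sinus_t10 = T.base_tissue_params("sinus").t10_ms + rng.normal(0, 20.0, n)
    cb = (1.0 - config.hematocrit) * cp_plasma(times, config.bolus)
    sig = _sinus_signal(cb, sinus_t10, config)
    sinus_enh = sig / sig0_ref(sinus_t10, config) - 1.0
    if sd > 0:
        sinus_enh = sinus_enh + rng.normal(0.0, sd, sinus_enh.shape)
    levels = sinus_enh[:, 1:].mean(axis=1)

    out = tab[["patient_id", "tissue", "true_slope_1e3"]].copy()
    out["slope_per_min"] = slopes
    out["slope_1e3"] = slopes * REPORT_SCALE
    out["n_voxels"] = 1
    out["t10_ms"] = tab.t10_ms.to_numpy() + rng.normal(0.0, 3.0, len(tab))
    out = out.merge(pd.DataFrame({"patient_id": cohort.covariates.patient_id,
                                  "sinus_level": levels}), on="patient_id")
    out = out.merge(cohort.covariates, on="patient_id")
    if not return_curves:
        return out

    curves = pd.DataFrame({
        "patient_id": np.repeat(tab.patient_id.to_numpy(), len(times)),
        "tissue": np.repeat(tab.tissue.to_numpy(), len(times)),
        "time_min": np.tile(times, len(tab)),
        "enhancement": enh.ravel(),
        "enhancement_1e3": enh.ravel() * REPORT_SCALE,
    }).merge(cohort.covariates, on="patient_id")
    return out, curves


def _sinus_signal(cb, t10_ms, config):
    from .forward import dce_signal_curve

    conc = np.broadcast_to(cb, (len(t10_ms), len(cb)))
    return dce_signal_curve(conc, np.asarray(t10_ms),
                            np.full(len(t10_ms), 1000.0), config)


def sig0_ref(t10_ms, config):
    from .forward import dce_signal_curve

    z = np.zeros((len(np.atleast_1d(t10_ms)), 1))
    return dce_signal_curve(z, np.asarray(t10_ms),
                            np.full(len(np.atleast_1d(t10_ms)), 1000.0),
                            config)


def sinus_series(cohort: Cohort, patient_id: int) -> EnhancementSeries:
    """Noise-free blood-pool enhancement series for one patient."""
    config = cohort.config
    cb = (1.0 - config.hematocrit) * cp_plasma(config.times_min, config.bolus)
    t10 = np.array([T.base_tissue_params("sinus").t10_ms])
    enh = (_sinus_signal(cb, t10, config) / sig0_ref(t10, config) - 1.0)[0]
    return EnhancementSeries("sinus", config.times_min, enh, 1)


def simulate_cognition(cohort: Cohort,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Append ACE-R scores (baseline and 1 year) to the covariate table.

    1-year ACE-R depends on baseline ACE-R, premorbid IQ (NART) and the
    patient's standardised true WMH leakage with a subtype-specific
    coefficient; scores truncate to [0, 100].  Patients without WMH have no
    leakage exposure and get NaN in ``wmh_true_slope_1e3``.
    """
    config = cohort.config
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    eff = cohort.truth.effects
    cp = cohort.truth.cognition
    cov = cohort.covariates.copy()

    wmh = (cohort.truth.table.query("tissue == 'wmh'")
           .set_index("patient_id").true_slope_1e3)
    leak = cov.patient_id.map(wmh)
    z = (leak - leak.mean()) / leak.std(ddof=0) if leak.std(ddof=0) > 0 \
        else leak * 0.0
    z_filled = z.fillna(0.0).to_numpy()

    base = (cp["base_intercept"] + cp["base_per_nart"] * cov.nart
            + cp["base_per_age5"] * cov.age5
            + rng.normal(0.0, cp["base_noise_sd"], len(cov)))
    base = np.clip(base, 0.0, 100.0)
    beta = np.where(cov.lacunar == 1, eff.beta_leak_lacunar,
                    eff.beta_leak_cortical)
    one_yr = (cp["oneyr_intercept"] + cp["oneyr_per_base"] * base
              + cp["oneyr_per_nart"] * cov.nart + beta * z_filled
              + rng.normal(0.0, cp["oneyr_noise_sd"], len(cov)))
    one_yr = np.clip(one_yr, 0.0, 100.0)

    cov["acer_baseline"] = base
    cov["acer_1yr"] = one_yr
    cov["wmh_true_slope_1e3"] = leak.to_numpy()
    return cov


def fig_profile_cohort(effects: CovariateEffects | None = None,
                       grid: tuple[int, int, int] = (40, 40, 40)) -> Cohort:
    """A small designed cohort for the contour-profile ordering checks:
    three patients per WMH-burden group (low 1-2, medium 3-4, high 5-6),
    other covariates held at reference values, noise off, and a grid large
    enough that all ten contours are populated."""
    effects = CovariateEffects.reference() if effects is None else effects
    faz = np.array([1, 2, 2, 3, 4, 4, 5, 6, 6])
    age = np.linspace(55.0, 80.0, len(faz))
    config = CohortConfig(n_patients=len(faz), grid_shape=grid,
                          snr=0.0, noise_model="none", region_noise_sd=0.0,
                          patient_slope_sd_1e3=0.0, seed=11)
    cov = _draw_covariates(config, effects, np.random.default_rng(11))
    cov["age_years"] = age
    cov["age5"] = (age - 65.0) / 5.0
    cov["fazekas_score"] = faz
    cov["stroke_subtype"] = "cortical"
    cov["lacunar"] = 0
    cov["hypertension"] = 0
    cov["map_mmHg"] = 100.0
    cov["map_c"] = 0.0
    cov["pulse_pressure_mmHg"] = 55.0
    cov["pp_c"] = 0.0
    cov["smoker"] = 0
    cov["has_old_infarct"] = 0
    return _rebuild_truth(config, effects, cov)


def _rebuild_truth(config: CohortConfig, effects: CovariateEffects,
                   cov: pd.DataFrame) -> Cohort:
    """Truth table for externally supplied covariates (no randomness)."""
    vocab = [t for t in T.tissue_vocabulary(config.n_contours)
             if t != "sinus"]
    rows = []
    for c in cov.itertuples():
        for tissue in vocab:
            wm_dependent = (tissue.startswith("contour_")
                            or tissue.startswith("wmh"))
            if c.fazekas_score == 0 and wm_dependent:
                continue
            if tissue == "old_infarct" and not c.has_old_infarct:
                continue
            s = (T.base_slope_1e3(tissue, effects.contour_gradient_1e3)
                 + effects.slope_effect(
                     tissue, age5=c.age5, fazekas=c.fazekas_score,
                     lacunar=c.lacunar, hypertension=c.hypertension,
                     map_c=c.map_c, pp_c=c.pp_c, smoker=c.smoker))
            p = T.base_tissue_params(tissue, c.fazekas_score)
            rows.append({
                "patient_id": c.patient_id, "tissue": tissue,
                "true_slope_1e3": s, "t10_ms": p.t10_ms, "m0": p.m0,
                "vp": p.vp, "md_true": p.md_true, "fa_true": p.fa_true,
            })
    table = pd.DataFrame(rows)
    ktrans, _ = solve_ktrans_for_slope(
        table.true_slope_1e3.to_numpy() / REPORT_SCALE,
        table.vp.to_numpy(), table.t10_ms.to_numpy(), config)
    table["ktrans_per_min"] = ktrans
    truth = CohortTruth(effects=effects, table=table,
                        patient_intercepts_1e3=np.zeros(len(cov)))
    return Cohort(config=config, covariates=cov, truth=truth)
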