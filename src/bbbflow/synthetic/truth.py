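"""Ground-truth tissue parameters and covariate effect sizes.

The generator is parameterised on the *enhancement-slope* scale (x 1e-3 per
minute), the scale on which leakage coefficients are conventionally
reported; Ktrans values are derived from target slopes through the forward
model's slope calibration.  The default effect sizes encode the published
cohort coefficients (per 5-year age increment, per Fazekas point, lacunar vs
cortical, hypertension, per-mmHg pressures, smoking) per tissue so that
parameter-recovery tests have literature-scale truth.

Compartment ordering preset: leakage is highest in intense WMH, lower in
less-intense WMH, and decays linearly across the NAWM contours toward the
distant-NAWM baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .. import labels as L

#: baseline enhancement slopes per tissue, x 1e-3 / min (reference patient:
#: age 65, Fazekas 0, cortical, normotensive, non-smoker)
BASE_SLOPES_1E3: dict[str, float] = {
    "csf": 1.8,
    "nawm": 0.5,
    "dgm": 0.4,
    "wmh": 1.05,
    "wmh_less_intense": 0.9,
    "wmh_intense": 1.2,
    "index_infarct": 2.5,
    "old_infarct": 2.1,
}

#: pre-contrast T1 (ms), equilibrium signal, plasma volume fraction,
#: MD (1e-9 m^2/s) and FA per compartment
_BASE_PARAMS = {
    # tissue:            (t10,  vp,    md,   fa)
    "csf":               (3500, 0.000, 3.00, 0.02),
    "nawm":              (700,  0.005, 0.80, 0.45),
    "dgm":               (1100, 0.005, 0.78, 0.20),
    "wmh":               (1000, 0.005, 1.10, 0.30),
    "wmh_less_intense":  (950,  0.005, 1.00, 0.35),
    "wmh_intense":       (1100, 0.005, 1.20, 0.25),
    "index_infarct":     (1200, 0.008, 1.50, 0.15),
    "old_infarct":       (1300, 0.008, 1.70, 0.12),
    "sinus":             (1400, 1.000, 2.00, 0.05),
}

#: per-contour gradients toward the WMH edge (per one-contour step)
CONTOUR_T10_STEP_MS = 3.0
CONTOUR_MD_STEP = 0.012
CONTOUR_FA_STEP = 0.006

#: per-Fazekas-point shifts of white-matter microstructure (WMH, contours,
#: NAWM): more WMH burden means more interstitial water (higher T1 and MD)
#: and less axonal coherence (lower FA)
FAZEKAS_T10_SHIFT_MS = 8.0
FAZEKAS_MD_SHIFT = 0.02
FAZEKAS_FA_SHIFT = -0.008

_WM_TISSUES = ("nawm", "wmh", "wmh_less_intense", "wmh_intense")


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth parameters of one compartment."""

    t10_ms: float
    m0: float
    ktrans_per_min: float
    vp: float
    md_true: float      # 1e-9 m^2/s reporting units
    fa_true: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ktrans_per_min) or self.ktrans_per_min < 0:
            raise ValueError("ktrans_per_min must be finite and >= 0")
        if self.t10_ms <= 0:
            raise ValueError("t10_ms must be positive")
        if self.m0 <= 0:
            raise ValueError("m0 must be positive")
        if not 0 <= self.vp <= 1:
            raise ValueError("vp must lie in [0, 1]")
        if self.md_true <= 0:
            raise ValueError("md_true must be positive")
        if not 0 <= self.fa_true < 1:
            raise ValueError("fa_true must lie in [0, 1)")


def _tissue_family(tissue: str) -> str:
    """Map a fine label to the effect family it inherits from."""
    if tissue.startswith("contour_"):
        return "nawm"
    if tissue in ("wmh_less_intense", "wmh_intense"):
        return "wmh"
    return tissue


def _per_tissue(**values: float) -> dict[str, float]:
    out = {t: 0.0 for t in L.MODEL_TISSUES}
    out.update(values)
    return out


@dataclass(frozen=True)
class CovariateEffects:
    """Linear covariate effects on the leakage slope, x 1e-3 per minute.

    Keys are the six model tissues; contours inherit the NAWM effects and
    the WMH intensity strata inherit the pooled-WMH effects.  ``beta_t10``
    (per ms deviation from the tissue mean) and ``beta_vif`` (per unit
    blood-pool enhancement) default to zero.  Cognition effects are per unit
    of standardised WMH leakage.
    """

    beta_age5: dict[str, float] = field(default_factory=dict)
    beta_fazekas: dict[str, float] = field(default_factory=dict)
    beta_subtype: dict[str, float] = field(default_factory=dict)
    beta_hypertension: dict[str, float] = field(default_factory=dict)
    beta_map: dict[str, float] = field(default_factory=dict)
    beta_pulse_pressure: dict[str, float] = field(default_factory=dict)
    beta_smoker: dict[str, float] = field(default_factory=dict)
    beta_t10: dict[str, float] = field(default_factory=dict)
    beta_vif: dict[str, float] = field(default_factory=dict)
    contour_gradient_1e3: float = 0.0099
    beta_leak_lacunar: float = -1.89
    beta_leak_cortical: float = -1.89

    def __post_init__(self) -> None:
        for name in ("beta_age5", "beta_fazekas", "beta_subtype",
                     "beta_hypertension", "beta_map", "beta_pulse_pressure",
                     "beta_smoker", "beta_t10", "beta_vif"):
            d = getattr(self, name)
            object.__setattr__(self, name, _per_tissue(**d))
            if not all(np.isfinite(list(getattr(self, name).values()))):
                raise ValueError(f"{name}: effects must be finite")
        if not np.isfinite([self.contour_gradient_1e3, self.beta_leak_lacunar,
                            self.beta_leak_cortical]).all():
            raise ValueError("effects must be finite")

    def slope_effect(self, tissue: str, *, age5: float, fazekas: float,
                     lacunar: float, hypertension: float, map_c: float,
                     pp_c: float, smoker: float) -> float:
        fam = _tissue_family(tissue)
        return (self.beta_age5[fam] * age5
                + self.beta_fazekas[fam] * fazekas
                + self.beta_subtype[fam] * lacunar
                + self.beta_hypertension[fam] * hypertension
                + self.beta_map[fam] * map_c
                + self.beta_pulse_pressure[fam] * pp_c
                + self.beta_smoker[fam] * smoker)

    @classmethod
    def reference(cls) -> "CovariateEffects":
        """Published-cohort effect sizes (x 1e-3 slope units)."""
        return cls(
            beta_age5=dict(nawm=0.016, dgm=0.025, csf=0.219, wmh=0.059,
                           index_infarct=0.045, old_infarct=0.049),
            beta_fazekas=dict(nawm=0.024, dgm=0.059, csf=0.205, wmh=0.104,
                              index_infarct=0.017, old_infarct=0.041),
            beta_subtype=dict(nawm=-0.110, dgm=-0.11, csf=0.363, wmh=-0.040,
                              index_infarct=-0.520, old_infarct=-0.430),
            beta_hypertension=dict(nawm=0.206, dgm=0.233, csf=0.338,
                                   wmh=0.256, index_infarct=0.677,
                                   old_infarct=0.472),
            beta_map=dict(nawm=-0.00105, dgm=0.00017, csf=0.016,
                          wmh=0.000368, index_infarct=-0.00298,
                          old_infarct=0.016),
            beta_pulse_pressure=dict(nawm=0.00121, dgm=0.0038, csf=0.017,
                                     wmh=0.00333, index_infarct=-0.00203,
                                     old_infarct=0.00261),
            beta_smoker=dict(nawm=-0.050, dgm=0.035, csf=-0.30, wmh=-0.110,
                             index_infarct=-0.040, old_infarct=-0.40),
        )

    @classmethod
    def null(cls) -> "CovariateEffects":
        """All effects zero (for type-I-error and null simulations)."""
        return cls(contour_gradient_1e3=0.0, beta_leak_lacunar=0.0,
                   beta_leak_cortical=0.0)


def tissue_vocabulary(n_contours: int = 10) -> list[str]:
    """All compartment names of a generated cohort, coarse to fine."""
    return (list(BASE_SLOPES_1E3) +
            [L.contour_name(k) for k in range(1, n_contours + 1)] + ["sinus"])


def base_slope_1e3(tissue: str, contour_gradient_1e3: float) -> float:
    """Baseline (reference-patient) slope for any compartment."""
    if tissue.startswith("contour_"):
        k = int(tissue.split("_")[1])
        # contour 1 hugs the WMH edge; gradient decays linearly outward
        n = 10
        return BASE_SLOPES_1E3["nawm"] + contour_gradient_1e3 * (n + 1 - k)
    if tissue == "sinus":
        return 0.0
    return BASE_SLOPES_1E3[tissue]


def base_tissue_params(tissue: str, fazekas: float = 0.0) -> TissueParams:
    """T10/M0/vp/MD/FA for a compartment, with Fazekas-dependent
    white-matter shifts applied; ktrans filled in later by calibration."""
    if tissue.startswith("contour_"):
        k = int(tissue.split("_")[1])
        t10, vp, md, fa = _BASE_PARAMS["nawm"]
        steps = 11 - k
        t10 = t10 + CONTOUR_T10_STEP_MS * steps
        md = md + CONTOUR_MD_STEP * steps
        fa = fa - CONTOUR_FA_STEP * steps
        family = "nawm"
    else:
        t10, vp, md, fa = _BASE_PARAMS[tissue]
        family = _tissue_family(tissue)
    if family in ("nawm", "wmh"):
        t10 += FAZEKAS_T10_SHIFT_MS * fazekas
        md += FAZEKAS_MD_SHIFT * fazekas
        fa = max(fa + FAZEKAS_FA_SHIFT * fazekas, 0.01)
    return TissueParams(t10_ms=t10, m0=1000.0, ktrans_per_min=0.0, vp=vp,
                        md_true=md, fa_true=fa)


def default_tissue_truth(n_contours: int = 10,
                         fazekas: float = 0.0) -> dict[str, TissueParams]:
    """Compartment -> parameters preset (ktrans left 0; the simulators
    derive it from target slopes via the forward-model calibration)."""
    return {t: base_tissue_params(t, fazekas)
            for t in tissue_vocabulary(n_contours)}


def with_ktrans(params: TissueParams, ktrans: float) -> TissueParams:
    return replace(params, ktrans_per_min=ktrans)
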