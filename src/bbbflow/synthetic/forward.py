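"""Patlak + SPGR forward model shared by all simulators.

Tissue contrast-agent concentration follows the Patlak low-permeability
model,

    C_t(t) = Ktrans * int_0^t C_p(tau) dtau + v_p * C_p(t),

with a plasma curve C_p that rises linearly to a first-pass peak and then
decays bi-exponentially (the blood pool declines slowly over the 24-minute
acquisition while leaky tissue keeps accumulating).  Concentration maps to
signal through the spoiled-gradient-echo equation with
``1/T1(t) = 1/T10 + r1 * C(t)``.

Both C_p and its running integral are analytic, so no quadrature is needed;
tests check the integral against numerical quadrature independently.
"""

from __future__ import annotations

import numpy as np

from ..config import BolusModel, CohortConfig
from ..relaxometry import spgr_signal


def cp_plasma(t_min, bolus: BolusModel) -> np.ndarray:
    """Plasma concentration (mM) at times ``t_min`` (minutes, >= 0)."""
    t = np.asarray(t_min, dtype=float)
    tp = bolus.peak_time_min
    up = bolus.peak_mM * t / tp
    dt = np.maximum(t - tp, 0.0)
    down = bolus.peak_mM * (
        bolus.frac_fast * np.exp(-dt / bolus.tau_fast_min)
        + (1 - bolus.frac_fast) * np.exp(-dt / bolus.tau_slow_min))
    return np.where(t <= tp, up, down)


def cp_plasma_integral(t_min, bolus: BolusModel) -> np.ndarray:
    """Running integral of :func:`cp_plasma` in mM * min (closed form)."""
    t = np.asarray(t_min, dtype=float)
    tp = bolus.peak_time_min
    a = bolus.peak_mM
    upslope_area = a * np.minimum(t, tp) ** 2 / (2 * tp)
    dt = np.maximum(t - tp, 0.0)
    tail = a * (
        bolus.frac_fast * bolus.tau_fast_min
        * (1 - np.exp(-dt / bolus.tau_fast_min))
        + (1 - bolus.frac_fast) * bolus.tau_slow_min
        * (1 - np.exp(-dt / bolus.tau_slow_min)))
    return upslope_area + np.where(t > tp, tail, 0.0)


def tissue_concentration(t_min, ktrans_per_min, vp, bolus: BolusModel):
    """Patlak tissue concentration (mM); parameters broadcast against time.

    ``ktrans_per_min`` and ``vp`` may be arrays with a trailing broadcast
    axis for time (shape ``(..., 1)`` against ``t_min`` of shape ``(n,)``).
    """
    cp = cp_plasma(t_min, bolus)
    icp = cp_plasma_integral(t_min, bolus)
    k = np.asarray(ktrans_per_min, dtype=float)
    v = np.asarray(vp, dtype=float)
    return k[..., None] * icp + v[..., None] * cp


def dce_signal_curve(conc_mM, t10_ms, m0, config: CohortConfig,
                     flip_deg: float | None = None) -> np.ndarray:
    """SPGR signal for a concentration time course.

    ``conc_mM`` has a trailing time axis; ``t10_ms`` and ``m0`` broadcast
    against its leading axes.  ``r1_relaxivity`` is per mM per second, so the
    relaxation-rate increment in 1/ms is ``r1 * C / 1000``.
    """
    c = np.asarray(conc_mM, dtype=float)
    t10 = np.asarray(t10_ms, dtype=float)[..., None]
    m0a = np.asarray(m0, dtype=float)[..., None]
    r1_total = 1.0 / t10 + config.r1_relaxivity * c / 1000.0
    flip = config.dynamic_flip_deg if flip_deg is None else flip_deg
    return spgr_signal(m0a, 1.0 / r1_total, config.tr_ms, flip)


def enhancement_curve(ktrans_per_min, vp, t10_ms, config: CohortConfig,
                      m0=1.0) -> np.ndarray:
    """Noise-free relative enhancement (S(t) - S_pre) / S_pre per tissue.

    Relative enhancement is independent of m0; the argument exists so the
    same path serves signal-level simulation.
    """
    t = config.times_min
    conc = tissue_concentration(t, ktrans_per_min, vp, config.bolus)
    k = np.asarray(ktrans_per_min, dtype=float)
    s = dce_signal_curve(conc, t10_ms, np.broadcast_to(m0, k.shape), config)
    s_pre = dce_signal_curve(np.zeros(k.shape + (1,)), t10_ms,
                             np.broadcast_to(m0, k.shape), config)
    return s / s_pre - 1.0


def slope_calibration(t10_ms, vp, config: CohortConfig,
                      fit_window_min=None,
                      ktrans_ref: float = 1e-3):
    """Affine map between Ktrans and the measured enhancement slope.

    Returns ``(slope0, kappa)`` such that the OLS enhancement slope of the
    forward model is ``slope0 + kappa * ktrans`` (exact up to the mild SPGR
    nonlinearity, which is negligible at these enhancement amplitudes).
    Used by the cohort generator to express covariate effects on the
    slope scale the models report.
    """
    from ..dce import ols_slopes

    t10 = np.asarray(t10_ms, dtype=float)
    v = np.broadcast_to(np.asarray(vp, dtype=float), t10.shape)
    zero = np.zeros_like(t10)
    e0 = enhancement_curve(zero, v, t10, config)
    e1 = enhancement_curve(zero + ktrans_ref, v, t10, config)
    s0 = ols_slopes(config.times_min, e0, fit_window_min)
    s1 = ols_slopes(config.times_min, e1, fit_window_min)
    kappa = (s1 - s0) / ktrans_ref
    return s0, kappa


def solve_ktrans_for_slope(target_slope, vp, t10_ms, config: CohortConfig,
                           fit_window_min=None, n_iter: int = 3):
    """Ktrans whose forward-model enhancement slope equals ``target_slope``.

    Starts from the affine calibration and Newton-refines against the true
    (mildly nonlinear) slope map; negative solutions clip to zero (leakage
    cannot be negative), so very low targets are met only approximately.
    Returns ``(ktrans, n_clipped)``.
    """
    from ..dce import ols_slopes

    target = np.asarray(target_slope, dtype=float)
    t10 = np.asarray(t10_ms, dtype=float)
    v = np.broadcast_to(np.asarray(vp, dtype=float), t10.shape)
    s0, kappa = slope_calibration(t10, v, config, fit_window_min)
    k = (target - s0) / kappa
    n_clipped = int(np.count_nonzero(k < 0))
    k = np.clip(k, 0.0, None)
    for _ in range(n_iter):
        e = enhancement_curve(k, v, t10, config)
        s = ols_slopes(config.times_min, e, fit_window_min)
        k = np.clip(k - (s - target) / kappa, 0.0, None)
    return k, n_clipped
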