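"""Voxelwise DCE simulation from a truth label map and tissue parameters."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .. import labels as L
from ..config import CohortConfig
from .forward import cp_plasma, dce_signal_curve, tissue_concentration

log = logging.getLogger(__name__)


@dataclass
class DceSeries:
    """Time-ordered stack of post-contrast volumes."""

    data: np.ndarray         # (*grid, n_dynamics)
    times_min: np.ndarray

    def __post_init__(self) -> None:
        if self.data.shape[-1] != len(self.times_min):
            raise ValueError("dynamic axis must match times")


@dataclass
class PreContrastPair:
    """The two pre-contrast spoiled-gradient-echo volumes."""

    low_flip: np.ndarray
    high_flip: np.ndarray
    flips_deg: tuple[float, float]


def _add_noise(vol, sigma, model, rng):
    if sigma <= 0 or model == "none":
        return vol
    if model == "gaussian":
        return vol + rng.normal(0.0, sigma, vol.shape)
    if model == "rician":
        # Gaussian noise on two quadrature channels -> Rician magnitude
        re = vol + rng.normal(0.0, sigma, vol.shape)
        im = rng.normal(0.0, sigma, vol.shape)
        return np.sqrt(re * re + im * im)
    raise ValueError(f"unknown noise model {model!r}")


def simulate_dce(truth_labels, tissue_params: dict, config: CohortConfig,
                 rng: np.random.Generator | None = None
                 ) -> tuple[DceSeries, PreContrastPair]:
    """Forward-simulate the dynamic series and the pre-contrast flip pair.

    ``truth_labels`` is a fine label volume (tissues + contours);
    ``tissue_params`` maps label names to :class:`TissueParams`.  Sinus
    voxels carry the whole-blood concentration ``(1 - Hct) * Cp`` directly;
    every other compartment follows the Patlak model.  Negative
    concentrations (possible only with pathological bolus settings) are
    clipped at zero and counted.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    lab = np.asarray(truth_labels)
    times = config.times_min
    nt = config.n_dynamics
    dyn = np.zeros(lab.shape + (nt,))
    lo = np.zeros(lab.shape)
    hi = np.zeros(lab.shape)
    f_lo, f_hi = config.flip_angles_deg
    n_clipped = 0

    for code in np.unique(lab):
        if code == L.BACKGROUND:
            continue
        name = L.label_name(int(code))
        p = tissue_params[name]
        if name == "sinus":
            conc = (1.0 - config.hematocrit) * cp_plasma(times, config.bolus)
        else:
            conc = tissue_concentration(
                times, np.float64(p.ktrans_per_min), np.float64(p.vp),
                config.bolus)
        neg = conc < 0
        if neg.any():
            n_clipped += int(neg.sum())
            conc = np.clip(conc, 0.0, None)
        mask = lab == code
        sig = dce_signal_curve(conc, np.float64(p.t10_ms), np.float64(p.m0),
                               config)
        dyn[mask, :] = sig
        lo[mask] = dce_signal_curve(np.zeros(1), np.float64(p.t10_ms),
                                    np.float64(p.m0), config, flip_deg=f_lo)[0]
        hi[mask] = dce_signal_curve(np.zeros(1), np.float64(p.t10_ms),
                                    np.float64(p.m0), config, flip_deg=f_hi)[0]

    if n_clipped:
        log.warning("simulate_dce: %d negative concentration samples clipped",
                    n_clipped)

    sigma = 0.0
    if config.snr > 0 and config.noise_model != "none":
        # SNR is defined against the mean pre-contrast high-flip brain signal
        ref = hi[lab != L.BACKGROUND]
        sigma = float(ref.mean()) / config.snr if ref.size else 0.0
    dyn = _add_noise(dyn, sigma, config.noise_model, rng)
    lo = _add_noise(lo, sigma, config.noise_model, rng)
    hi = _add_noise(hi, sigma, config.noise_model, rng)

    return (DceSeries(data=dyn, times_min=times),
            PreContrastPair(low_flip=lo, high_flip=hi,
                            flips_deg=config.flip_angles_deg))
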