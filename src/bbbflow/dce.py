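"""Enhancement extraction and slope-based leakage quantification.

The leakage metric is deliberately model-free: the ordinary least-squares
slope of relative signal enhancement against time over the late acquisition
window, per tissue.  Slow blood-brain-barrier leak shows up as a small
positive slope; no pharmacokinetic parameters are fitted here (the Patlak
model lives only in the simulator and in test oracles).

Enhancement is relative: ``(S(t) - S_pre) / S_pre`` per voxel, which removes
equilibrium-signal and coil-gain differences between tissues and patients.
A raw-difference mode is available via ``normalize=False``.

Slopes are conventionally reported as "x 1e-3 per minute"; tables carry both
the raw ``slope_per_min`` and the scaled ``slope_1e3`` column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import labels as L

log = logging.getLogger(__name__)

REPORT_SCALE = 1e3

#: start (minutes) of the post-first-pass window over which leak-driven
#: tissue enhancement rises monotonically while the blood pool declines;
#: before this the intravascular washout can still dominate low-Ktrans
#: tissue curves
LATE_WINDOW_START_MIN = 6.0


@dataclass
class EnhancementSeries:
    """Mean enhancement time course of one tissue label."""

    label: str
    times_min: np.ndarray
    enhancement: np.ndarray
    n_voxels: int

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.enhancement = np.asarray(self.enhancement, dtype=float)
        if self.times_min.ndim != 1 or self.times_min.shape != self.enhancement.shape:
            raise ValueError("times and enhancement must be equal-length 1-D")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.n_voxels <= 0:
            raise ValueError("n_voxels must be positive")


def extract_enhancement(dce_data, times_min, label_map, baseline,
                        normalize: bool = True) -> list[EnhancementSeries]:
    """Per-label mean enhancement curves from a dynamic 4-D volume.

    ``dce_data`` has shape ``(*grid, n_times)``; ``label_map`` is an integer
    volume on the same grid; ``baseline`` is the pre-contrast volume.  Voxels
    with non-positive baseline are excluded (and counted) because relative
    enhancement is undefined there.  Empty labels are omitted with a log
    entry.
    """
    dce = np.asarray(dce_data, dtype=float)
    lab = np.asarray(label_map)
    base = np.asarray(baseline, dtype=float)
    if dce.shape[:-1] != lab.shape or base.shape != lab.shape:
        raise ValueError("dce, label_map and baseline must share one grid")
    times = np.asarray(times_min, dtype=float)
    if times.shape[0] != dce.shape[-1]:
        raise ValueError("times length must match the dynamic axis")

    out: list[EnhancementSeries] = []
    for code in np.unique(lab):
        if code == L.BACKGROUND:
            continue
        mask = lab == code
        ok = mask & (base > 0)
        n_excl = int(np.count_nonzero(mask) - np.count_nonzero(ok))
        if n_excl:
            log.info("extract_enhancement: %s: %d voxels with baseline <= 0 "
                     "excluded", L.label_name(int(code)), n_excl)
        n = int(np.count_nonzero(ok))
        if n == 0:
            log.info("extract_enhancement: label %s empty, omitted",
                     L.label_name(int(code)))
            continue
        s = dce[ok, :]                      # (n_voxels, n_times)
        b = base[ok][:, None]
        enh = (s - b) / b if normalize else (s - b)
        out.append(EnhancementSeries(L.label_name(int(code)), times,
                                     enh.mean(axis=0), n))
    return out


def extract_vif(dce_data, times_min, sinus_mask, baseline) -> EnhancementSeries:
    """Blood-pool (vascular input) enhancement from the sagittal sinus.

    The sinus reference is mandatory for the downstream models (intravascular
    contrast is a required adjuster), so an empty mask is an error.
    """
    sinus = np.asarray(sinus_mask, bool)
    if not sinus.any():
        raise ValueError("sinus mask is empty; the intravascular reference "
                         "is required")
    lab = np.where(sinus, L.SINUS, L.BACKGROUND)
    series = extract_enhancement(dce_data, times_min, lab, baseline)
    if not series:
        raise ValueError("sinus mask has no voxels with positive baseline")
    return series[0]


def vif_level(series: EnhancementSeries, skip_first: int = 1) -> float:
    """Summary blood-pool level: mean enhancement after the bolus frame(s).

    This scalar is the ``sinus_level`` covariate of the slope table.
    """
    return float(series.enhancement[skip_first:].mean())


def _window_mask(times: np.ndarray, fit_window_min) -> np.ndarray:
    if fit_window_min is None:
        # default: all frames after the first (bolus-dominated) frame
        m = np.ones_like(times, bool)
        m[0] = False
        return m
    lo, hi = fit_window_min
    return (times >= lo) & (times <= hi)


def ols_slopes(times_min, values, fit_window_min=None) -> np.ndarray:
    """Vectorised OLS slope of ``values`` (…, n_times) against time.

    The same estimator as :func:`estimate_slope`, batched over leading axes.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(values, dtype=float)
    m = _window_mask(t, fit_window_min)
    if np.count_nonzero(m) < 3:
        raise ValueError("need at least 3 timepoints in the fit window")
    tw = t[m]
    yw = y[..., m]
    tc = tw - tw.mean()
    return (yw * tc).sum(axis=-1) / (tc * tc).sum()


def estimate_slope(series: EnhancementSeries, fit_window_min=None) -> float:
    """Enhancement slope (per minute) of one tissue series.

    Default window: every frame after the first post-injection frame, so the
    first-pass bolus does not dominate the late, leak-driven trend.
    """
    return float(ols_slopes(series.times_min, series.enhancement,
                            fit_window_min))


def build_slope_table(per_patient_series: dict,
                      covariates: pd.DataFrame,
                      sinus_levels: dict,
                      t10_means: dict | None = None,
                      fit_window_min=None) -> pd.DataFrame:
    """Assemble the long per-patient x per-tissue table the models consume.

    ``per_patient_series`` maps patient_id -> list of
    :class:`EnhancementSeries`; ``sinus_levels`` maps patient_id -> blood-pool
    level; ``t10_means`` (optional) maps (patient_id, label) -> mean tissue
    T10 in ms.  Missing covariates are kept as NaN and counted, never
    dropped silently.
    """
    cov = covariates.set_index("patient_id")
    rows = []
    for pid, series_list in per_patient_series.items():
        if not series_list:
            raise ValueError(f"patient {pid!r} has no tissue series")
        for s in series_list:
            t10 = np.nan
            if t10_means is not None:
                t10 = t10_means.get((pid, s.label), np.nan)
            slope = estimate_slope(s, fit_window_min)
            rows.append({
                "patient_id": pid,
                "tissue": s.label,
                "slope_per_min": slope,
                "slope_1e3": slope * REPORT_SCALE,
                "n_voxels": s.n_voxels,
                "sinus_level": sinus_levels.get(pid, np.nan),
                "t10_ms": t10,
            })
    table = pd.DataFrame(rows)
    table = table.join(cov, on="patient_id")
    n_missing = int(table.isna().sum().sum())
    if n_missing:
        log.info("build_slope_table: %d missing values retained", n_missing)
    return table
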