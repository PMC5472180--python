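"""Configuration objects for simulation and pipeline runs.

All physical quantities carry explicit units in their field names.  Validation
happens eagerly in ``__post_init__`` so a bad configuration fails before any
compute, naming the offending field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml


class ConfigError(ValueError):
    """Invalid configuration; the message names the field."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class BolusModel:
    """Plasma contrast-agent curve: linear upslope to a peak, then
    bi-exponential decay — the observed blood-pool shape (first-pass peak
    followed by a slow decline over the 24-minute acquisition).

    Concentrations are plasma concentrations in mM; the blood-pool (sinus)
    signal uses whole-blood concentration ``(1 - hematocrit) * cp``.
    """

    peak_mM: float = 5.0          # plasma peak after 0.1 mmol/kg bolus
    peak_time_min: float = 1.0
    frac_fast: float = 0.6
    tau_fast_min: float = 2.0
    tau_slow_min: float = 60.0

    def __post_init__(self) -> None:
        _require(self.peak_mM > 0, "peak_mM", "must be positive")
        _require(self.peak_time_min > 0, "peak_time_min", "must be positive")
        _require(0 <= self.frac_fast <= 1, "frac_fast", "must be in [0, 1]")
        _require(self.tau_fast_min > 0, "tau_fast_min", "must be positive")
        _require(self.tau_slow_min > 0, "tau_slow_min", "must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Acquisition + simulation parameters for one synthetic cohort."""

    n_patients: int = 30
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_dynamics: int = 20
    dynamic_interval_min: float = 1.2     # 20 frames span 24 minutes
    flip_angles_deg: tuple[float, float] = (2.0, 12.0)
    dynamic_flip_deg: float = 12.0        # post-contrast T1-weighted flip
    tr_ms: float = 8.0
    r1_relaxivity: float = 3.6            # gadoterate at 1.5 T, /mM/s
    hematocrit: float = 0.45
    bolus: BolusModel = field(default_factory=BolusModel)
    snr: float = 40.0                     # image-domain SNR (0 disables noise)
    noise_model: str = "rician"           # "rician" | "gaussian" | "none"
    region_noise_sd: float = 0.001        # sd of region-mean enhancement noise
    patient_slope_sd_1e3: float = 0.1     # patient random intercept, x1e-3/min
    n_contours: int = 10
    contour_width_voxels: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_patients >= 0, "n_patients", "must be >= 0")
        _require(len(self.grid_shape) == 3 and all(s > 0 for s in self.grid_shape),
                 "grid_shape", "must be three positive extents")
        _require(all(v > 0 for v in self.voxel_size_mm),
                 "voxel_size_mm", "must be positive")
        _require(self.n_dynamics >= 3, "n_dynamics", "must be >= 3")
        _require(self.dynamic_interval_min > 0, "dynamic_interval_min",
                 "must be positive")
        lo, hi = self.flip_angles_deg
        _require(lo != hi, "flip_angles_deg", "flip angles must be distinct")
        _require(0 < lo < 90 and 0 < hi < 90, "flip_angles_deg",
                 "flip angles must lie in (0, 90) degrees")
        _require(0 < self.dynamic_flip_deg <= 90, "dynamic_flip_deg",
                 "must lie in (0, 90] degrees")
        _require(self.tr_ms > 0, "tr_ms", "must be positive")
        _require(self.r1_relaxivity > 0, "r1_relaxivity", "must be positive")
        _require(0 <= self.hematocrit < 1, "hematocrit", "must be in [0, 1)")
        _require(self.snr >= 0, "snr", "must be >= 0")
        _require(self.noise_model in ("rician", "gaussian", "none"),
                 "noise_model", "must be 'rician', 'gaussian' or 'none'")
        _require(self.region_noise_sd >= 0, "region_noise_sd", "must be >= 0")
        _require(self.n_contours >= 1, "n_contours", "must be >= 1")
        _require(self.contour_width_voxels >= 1, "contour_width_voxels",
                 "must be >= 1")

    @property
    def times_min(self):
        """Mid-frame acquisition times of the dynamic series, minutes after
        injection (frame i acquired at (i+1) * interval)."""
        import numpy as np

        return (np.arange(self.n_dynamics) + 1) * self.dynamic_interval_min

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CohortConfig":
        d = dict(d)
        if "bolus" in d and isinstance(d["bolus"], dict):
            d["bolus"] = BolusModel(**d["bolus"])
        for key in ("grid_shape", "voxel_size_mm", "flip_angles_deg"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
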