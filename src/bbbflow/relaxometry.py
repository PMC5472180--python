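"""Variable-flip-angle T1 mapping from two spoiled-gradient-echo volumes.

The steady-state SPGR signal is

    S = M0 * sin(a) * (1 - E1) / (1 - cos(a) * E1),   E1 = exp(-TR / T1),

which linearises as S/sin(a) = E1 * S/tan(a) + M0 * (1 - E1).  With exactly
two flip angles the two-point line through (S/tan, S/sin) gives E1 as its
slope and M0 from its intercept — an exact inversion, so no iterative fit is
needed.  No B1 correction is applied; flip angles are taken at face value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

#: admissible T1 range (ms); brackets brain tissue and CSF generously
T1_VALID_RANGE_MS = (50.0, 10000.0)


def spgr_signal(m0, t1_ms, tr_ms, flip_deg):
    """Steady-state spoiled gradient-echo signal.

    Parameters broadcast; ``t1_ms`` and ``tr_ms`` must be positive,
    ``flip_deg`` in [0, 90].
    """
    m0 = np.asarray(m0, dtype=float)
    t1_ms = np.asarray(t1_ms, dtype=float)
    if np.any(t1_ms <= 0):
        raise ValueError("t1_ms must be strictly positive")
    if tr_ms <= 0:
        raise ValueError("tr_ms must be strictly positive")
    flip_deg = np.asarray(flip_deg, dtype=float)
    if np.any(flip_deg < 0) or np.any(flip_deg > 90):
        raise ValueError("flip_deg must lie in [0, 90]")
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-tr_ms / t1_ms)
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - np.cos(a) * e1)


@dataclass
class T10Map:
    """Pre-contrast T1 and equilibrium-signal maps with a validity mask.

    Voxels where the two-point inversion is inadmissible (E1 outside (0, 1),
    non-positive signals, or T1 outside the physiological bracket) are flagged
    invalid; their values are NaN, never silently zero.
    """

    t10_ms: np.ndarray
    m0: np.ndarray
    valid: np.ndarray

    @property
    def n_invalid(self) -> int:
        return int(self.valid.size - np.count_nonzero(self.valid))


def fit_t10_vfa(signal_lowflip, signal_highflip, flips_deg, tr_ms) -> T10Map:
    """Two-point VFA inversion of the SPGR equation, voxelwise.

    ``flips_deg`` pairs with the two volumes in order.  The system is exactly
    determined, so noiseless inputs invert to machine precision.
    """
    s1 = np.asarray(signal_lowflip, dtype=float)
    s2 = np.asarray(signal_highflip, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError(
            f"flip-angle volumes differ in shape: {s1.shape} vs {s2.shape}")
    a1, a2 = (np.deg2rad(f) for f in flips_deg)
    if a1 == a2:
        raise ValueError("flip angles must be distinct")
    if tr_ms <= 0:
        raise ValueError("tr_ms must be strictly positive")

    with np.errstate(divide="ignore", invalid="ignore"):
        y1, x1 = s1 / np.sin(a1), s1 / np.tan(a1)
        y2, x2 = s2 / np.sin(a2), s2 / np.tan(a2)
        dx = x2 - x1
        e1 = np.where(dx != 0, (y2 - y1) / dx, np.nan)
        t1 = -tr_ms / np.log(e1)
        m0 = (y1 - e1 * x1) / (1.0 - e1)

    valid = (
        np.isfinite(e1) & (e1 > 0) & (e1 < 1)
        & (s1 > 0) & (s2 > 0)
        & np.isfinite(t1)
        & (t1 >= T1_VALID_RANGE_MS[0]) & (t1 <= T1_VALID_RANGE_MS[1])
    )
    t1 = np.where(valid, t1, np.nan)
    m0 = np.where(valid, m0, np.nan)
    n_bad = valid.size - int(np.count_nonzero(valid))
    if n_bad:
        log.info("fit_t10_vfa: %d/%d voxels inadmissible", n_bad, valid.size)
    return T10Map(t10_ms=t1, m0=m0, valid=valid)
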