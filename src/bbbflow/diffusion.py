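"""Diffusion-tensor fitting and the MD / FA scalar invariants.

The tensor is fitted voxelwise by log-linear least squares:
``ln S = ln S0 - b g^T D g`` is linear in the six unique tensor elements and
``ln S0``, so one pseudo-inverse serves every voxel.  Weighted or nonlinear
fitting would matter at very low SNR only and is out of scope.

Mean diffusivity is reported in the conventional 1e-9 m^2/s units (internal
tensors are mm^2/s; 1e-3 mm^2/s == 1 in reporting units).  Voxels with
non-positive signals or negative eigenvalues are flagged invalid and excluded
from summaries rather than clipped — counts are logged, never hidden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

#: mm^2/s -> 1e-9 m^2/s
MD_REPORT_SCALE = 1e3


def check_gradient_scheme(bvals, bvecs) -> tuple[np.ndarray, np.ndarray]:
    """Validate an FSL-style scheme: >= 1 b=0 volume and >= 6 distinct
    non-collinear diffusion directions."""
    b = np.asarray(bvals, dtype=float).ravel()
    g = np.asarray(bvecs, dtype=float)
    if g.shape == (3, b.size):
        g = g.T
    if g.shape != (b.size, 3):
        raise ValueError(f"bvecs shape {g.shape} does not match {b.size} bvals")
    dwi = b > 0
    if not (~dwi).any():
        raise ValueError("gradient scheme needs at least one b=0 volume")
    gd = g[dwi]
    # rank of the quadratic-form design decides whether D is identifiable
    q = _design_rows(np.ones(gd.shape[0]), gd)
    if np.linalg.matrix_rank(q) < 6:
        raise ValueError("need >= 6 non-collinear diffusion directions")
    norms = np.linalg.norm(gd, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero gradient vector with nonzero b-value")
    return b, g


def _design_rows(b, g):
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.stack([b * gx * gx, b * gy * gy, b * gz * gz,
                     2 * b * gx * gy, 2 * b * gx * gz, 2 * b * gy * gz],
                    axis=1)


def _six_to_tensor(d6):
    out = np.empty(d6.shape[:-1] + (3, 3))
    out[..., 0, 0] = d6[..., 0]
    out[..., 1, 1] = d6[..., 1]
    out[..., 2, 2] = d6[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = d6[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = d6[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = d6[..., 5]
    return out


@dataclass
class TensorMap:
    """Voxelwise diffusion tensors with sorted eigenvalues and validity."""

    tensor: np.ndarray        # (..., 3, 3), mm^2/s
    eigenvalues: np.ndarray   # (..., 3), sorted descending
    s0: np.ndarray
    valid: np.ndarray         # log-fit admissible
    nonneg: np.ndarray        # additionally, all eigenvalues >= 0

    @property
    def n_negative_eig(self) -> int:
        return int(np.count_nonzero(self.valid & ~self.nonneg))


def fit_tensor(dwi, bvals, bvecs) -> TensorMap:
    """Log-linear least-squares tensor fit of a (..., n_volumes) stack."""
    b, g = check_gradient_scheme(bvals, bvecs)
    data = np.asarray(dwi, dtype=float)
    if data.shape[-1] != b.size:
        raise ValueError("dwi last axis must match the number of b-values")

    design = np.concatenate([np.ones((b.size, 1)), -_design_rows(b, g)],
                            axis=1)                     # (nvol, 7)
    pinv = np.linalg.pinv(design)

    valid = np.all(data > 0, axis=-1)
    logs = np.log(np.where(data > 0, data, 1.0))
    coef = logs @ pinv.T                                # (..., 7)
    tensor = _six_to_tensor(coef[..., 1:])
    evals = np.linalg.eigvalsh(tensor)[..., ::-1]       # descending
    nonneg = np.all(evals >= 0, axis=-1)
    n_bad = int(np.count_nonzero(valid & ~nonneg))
    if n_bad:
        log.info("fit_tensor: %d voxels with negative eigenvalues flagged",
                 n_bad)
    return TensorMap(tensor=tensor, eigenvalues=evals,
                     s0=np.exp(coef[..., 0]), valid=valid, nonneg=nonneg)


def compute_md(eigenvalues) -> np.ndarray:
    """Mean diffusivity, (l1+l2+l3)/3, in the units of the eigenvalues."""
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.shape[-1] != 3:
        raise ValueError("expected three eigenvalues on the last axis")
    return ev.mean(axis=-1)


def compute_fa(eigenvalues) -> np.ndarray:
    """Fractional anisotropy in [0, 1]; NaN where all eigenvalues vanish."""
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.shape[-1] != 3:
        raise ValueError("expected three eigenvalues on the last axis")
    mean = ev.mean(axis=-1, keepdims=True)
    num = np.sqrt(1.5) * np.linalg.norm(ev - mean, axis=-1)
    den = np.linalg.norm(ev, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(den > 0, num / den, np.nan)
    n_undef = int(np.count_nonzero(den == 0))
    if n_undef:
        log.info("compute_fa: %d all-zero voxels undefined", n_undef)
    return fa


def axisymmetric_eigenvalues(md, fa) -> tuple[float, float, float]:
    """Eigenvalues (l_par, l_perp, l_perp) of the prolate axisymmetric tensor
    with exactly the requested MD and FA.

    With ``l_par = MD (1 + 2a)`` and ``l_perp = MD (1 - a)`` one gets
    ``FA = sqrt(3) a / sqrt(1 + 2 a^2)``, inverted in closed form as
    ``a = FA / sqrt(3 - 2 FA^2)``; ``FA < 1`` keeps ``l_perp > 0``.
    """
    if not 0 <= fa < 1:
        raise ValueError("fa must lie in [0, 1)")
    if md <= 0:
        raise ValueError("md must be positive")
    a = fa / np.sqrt(3.0 - 2.0 * fa * fa)
    return md * (1 + 2 * a), md * (1 - a), md * (1 - a)
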