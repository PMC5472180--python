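"""Diffusion-weighted simulation from per-compartment axisymmetric tensors.

Each compartment gets the prolate axisymmetric tensor matching its true
(MD, FA) exactly (closed-form construction); the principal axis is the z
axis by default.  Signal follows the monoexponential tensor model
``S = S0 * exp(-b g^T D g)``.
"""

from __future__ import annotations

import numpy as np

from .. import labels as L
from ..diffusion import (MD_REPORT_SCALE, axisymmetric_eigenvalues,
                         check_gradient_scheme)


def default_gradient_scheme(n_directions: int = 12, bval: float = 1000.0,
                            seed: int = 7):
    """A b=0 volume plus ``n_directions`` unit vectors spread on the sphere
    (electrostatic-style via seeded random + normalisation is adequate for
    simulation; >= 6 required)."""
    if n_directions < 6:
        raise ValueError("need at least 6 diffusion directions")
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_directions, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    bvals = np.concatenate([[0.0], np.full(n_directions, bval)])
    bvecs = np.concatenate([[[0.0, 0.0, 0.0]], v])
    return bvals, bvecs


def axisymmetric_tensor(md_report, fa, axis=(0.0, 0.0, 1.0)) -> np.ndarray:
    """3x3 tensor (mm^2/s) with the requested MD (reporting units) and FA."""
    l_par, l_perp, _ = axisymmetric_eigenvalues(md_report / MD_REPORT_SCALE,
                                                fa)
    n = np.asarray(axis, dtype=float)
    n /= np.linalg.norm(n)
    return l_perp * np.eye(3) + (l_par - l_perp) * np.outer(n, n)


def simulate_dwi(truth_labels, tissue_params: dict, bvals, bvecs,
                 noise_sd: float = 0.0,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate a (*grid, n_volumes) DWI stack from the truth label map."""
    b, g = check_gradient_scheme(bvals, bvecs)
    lab = np.asarray(truth_labels)
    out = np.zeros(lab.shape + (b.size,))
    for code in np.unique(lab):
        if code == L.BACKGROUND:
            continue
        p = tissue_params[L.label_name(int(code))]
        d = axisymmetric_tensor(p.md_true, p.fa_true)
        atten = np.exp(-b * np.einsum("ij,jk,ik->i", g, d, g))
        out[lab == code, :] = p.m0 * atten
    if noise_sd > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        re = out + rng.normal(0.0, noise_sd, out.shape)
        im = rng.normal(0.0, noise_sd, out.shape)
        out = np.sqrt(re * re + im * im)
    return out
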