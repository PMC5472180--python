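"""Synthetic single-patient anatomy: nested compartments on a voxel grid.

The phantom is deliberately schematic — an ellipsoidal brain with a CSF rim,
a central WMH blob (intense core inside a less-intense shell) whose size
grows with the Fazekas score, surrounding NAWM, a deep-grey blob, an index
infarct, an optional old infarct, and a tubular sagittal-sinus segment.  It
carries no real neuroanatomy; its job is to give every compartment enough
voxels, with the WMH embedded in NAWM so that concentric contours exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import labels as L
from ..config import CohortConfig
from ..contours import geodesic_distance_voxels, make_contours, merge_tissues


@dataclass
class AnatomyMasks:
    """Binary compartment masks (mutually disjoint) plus helper volumes."""

    csf: np.ndarray
    nawm: np.ndarray
    dgm: np.ndarray
    wmh: np.ndarray
    wmh_core: np.ndarray          # truth "intense" subset of wmh
    index_infarct: np.ndarray
    old_infarct: np.ndarray
    sinus: np.ndarray
    flair: np.ndarray             # synthetic FLAIR-like volume for the split

    @property
    def brain(self) -> np.ndarray:
        return (self.csf | self.nawm | self.dgm | self.wmh
                | self.index_infarct | self.old_infarct | self.sinus)

    def merged_labels(self) -> np.ndarray:
        return merge_tissues(self.csf, self.nawm, self.dgm, self.wmh,
                             self.index_infarct, self.old_infarct, self.sinus)

    def truth_labels(self, n_contours: int = 10,
                     width_voxels: int = 2) -> np.ndarray:
        """Ground-truth fine label map: WMH split by the core mask and NAWM
        subdivided into contours (the same geometry the analysis should
        recover)."""
        lab = self.merged_labels()
        lab[self.wmh_core] = L.WMH_INTENSE
        cl = make_contours(self.wmh, self.nawm & ~self.wmh,
                           n_contours, width_voxels)
        ring = cl.labels > L.CONTOUR_BASE
        lab[ring] = cl.labels[ring]
        return lab


def _ellipsoid(grid, center, semiaxes) -> np.ndarray:
    coords = np.indices(grid).astype(float)
    rho2 = sum(((coords[i] - center[i]) / semiaxes[i]) ** 2 for i in range(3))
    return rho2 <= 1.0


def wmh_radius_voxels(fazekas_score: float) -> float:
    """WMH blob radius; zero at Fazekas 0, growing with burden."""
    if fazekas_score <= 0:
        return 0.0
    # min 1.7 so even Fazekas 1 has a core *and* a shell on a
    # half-integer-centred grid (nearest voxels sit ~0.87 from the centre)
    return 1.35 + 0.35 * fazekas_score


def generate_anatomy(config: CohortConfig, fazekas_score: int,
                     include_old_infarct: bool = False,
                     rng: np.random.Generator | None = None,
                     min_margin_voxels: int = 4) -> AnatomyMasks:
    """Build one patient's compartment masks.

    ``min_margin_voxels`` guards against grids too small to leave NAWM
    around the WMH: generation fails if the largest geodesic NAWM distance
    from the WMH edge falls below it (so at least two default-width contours
    exist).  Far contour rings may still be empty on small grids once NAWM
    is exhausted — that is legal and logged downstream.
    """
    if not 0 <= int(fazekas_score) <= 6:
        raise ValueError("fazekas_score must lie in {0..6}")
    rng = np.random.default_rng(0) if rng is None else rng
    grid = tuple(config.grid_shape)
    center = tuple((s - 1) / 2.0 for s in grid)
    semi = tuple(s / 2.0 - 1.0 for s in grid)

    coords = np.indices(grid).astype(float)
    rho = np.sqrt(sum(((coords[i] - center[i]) / semi[i]) ** 2
                      for i in range(3)))
    brain = rho <= 1.0
    interior = rho <= 0.85
    csf = brain & ~interior

    # sagittal sinus: a tube along the z axis at the posterior interior edge
    ys = center[1] + 0.62 * semi[1]
    r2 = ((coords[0] - center[0]) ** 2 + (coords[1] - ys) ** 2)
    sinus = (r2 <= 1.3 ** 2) & interior

    r_wmh = wmh_radius_voxels(fazekas_score)
    if r_wmh > 0:
        d = np.sqrt(sum((coords[i] - center[i]) ** 2 for i in range(3)))
        wmh = (d <= r_wmh) & interior
        core = (d <= max(0.55 * r_wmh, 0.9)) & interior
    else:
        wmh = np.zeros(grid, bool)
        core = np.zeros(grid, bool)

    dgm_c = (center[0], center[1] - 0.45 * semi[1], center[2])
    dgm = _ellipsoid(grid, dgm_c, (2.0, 2.0, 2.0)) & interior
    idx_c = (center[0] + 0.45 * semi[0], center[1], center[2] + 0.15 * semi[2])
    index_infarct = _ellipsoid(grid, idx_c, (1.6, 1.6, 1.6)) & interior
    old_c = (center[0] - 0.45 * semi[0], center[1], center[2] - 0.15 * semi[2])
    old_infarct = (_ellipsoid(grid, old_c, (1.4, 1.4, 1.4)) & interior
                   if include_old_infarct else np.zeros(grid, bool))

    other = sinus | dgm | index_infarct | old_infarct
    wmh &= ~other
    core &= wmh
    nawm = interior & ~(wmh | other)

    if wmh.any():
        dist = geodesic_distance_voxels(wmh, nawm | wmh, connectivity=6)
        reach = dist[nawm & np.isfinite(dist)]
        max_reach = float(reach.max()) if reach.size else 0.0
        if max_reach < min_margin_voxels:
            raise ValueError(
                f"grid {grid} too small: only {max_reach:.0f} voxels of NAWM "
                f"beyond the WMH edge; need >= {min_margin_voxels}")

    flair = np.where(brain, 1.0, 0.0)
    flair[csf] = 0.3
    flair[wmh] = 1.5
    flair[core] = 2.0
    flair = flair + rng.normal(0.0, 0.02, grid) * brain

    return AnatomyMasks(csf=csf, nawm=nawm, dgm=dgm, wmh=wmh, wmh_core=core,
                        index_infarct=index_infarct, old_infarct=old_infarct,
                        sinus=sinus, flair=flair)
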