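"""Tissue label merging, WMH intensity split, and concentric NAWM contours.

The contours subdivide normal-appearing white matter into rings of fixed
width (in voxels) expanding outward from the WMH edge: ring ``k`` holds the
NAWM voxels whose geodesic-within-NAWM city-block distance ``d`` from the WMH
set satisfies ``(k-1)*width < d <= k*width``.  Distance is accumulated by
iterated morphological dilation restricted to the NAWM mask at every step, so
rings never leak across CSF or grey matter and re-enter.  NAWM beyond the
last ring is ``distant-NAWM``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import labels as L

log = logging.getLogger(__name__)

#: merge precedence, highest first
_PRECEDENCE = (
    L.INDEX_INFARCT,
    L.OLD_INFARCT,
    "wmh",          # placeholder; WMH enters as a single mask here
    L.DGM,
    L.CSF,
    L.SINUS,
    L.NAWM,
)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def _check_same_grid(masks: dict[str, np.ndarray]) -> tuple[int, ...]:
    shapes = {name: m.shape for name, m in masks.items()}
    uniq = set(shapes.values())
    if len(uniq) > 1:
        raise ValueError(f"masks are not on one grid: {shapes}")
    return next(iter(uniq))


def merge_tissues(csf, nawm, dgm, wmh, index_infarct, old_infarct,
                  sinus) -> np.ndarray:
    """Merge possibly overlapping binary masks into one exclusive label map.

    Overlaps resolve by precedence
    index infarct > old infarct > WMH > DGM > CSF > sinus > NAWM;
    overlap counts are logged.  The WMH mask is labelled ``WMH_LESS`` pending
    the intensity split.  Returns an int16 label volume.
    """
    masks = {
        "index_infarct": np.asarray(index_infarct, bool),
        "old_infarct": np.asarray(old_infarct, bool),
        "wmh": np.asarray(wmh, bool),
        "dgm": np.asarray(dgm, bool),
        "csf": np.asarray(csf, bool),
        "sinus": np.asarray(sinus, bool),
        "nawm": np.asarray(nawm, bool),
    }
    shape = _check_same_grid(masks)
    codes = {
        "index_infarct": L.INDEX_INFARCT, "old_infarct": L.OLD_INFARCT,
        "wmh": L.WMH_LESS, "dgm": L.DGM, "csf": L.CSF,
        "sinus": L.SINUS, "nawm": L.NAWM,
    }
    out = np.zeros(shape, dtype=np.int16)
    claimed = np.zeros(shape, dtype=bool)
    n_overlap = 0
    for name in ("index_infarct", "old_infarct", "wmh", "dgm", "csf",
                 "sinus", "nawm"):
        m = masks[name]
        n_overlap += int(np.count_nonzero(m & claimed))
        take = m & ~claimed
        out[take] = codes[name]
        claimed |= m
    if n_overlap:
        log.info("merge_tissues: %d overlapping voxels resolved by precedence",
                 n_overlap)
    return out


def split_wmh_intensity(wmh_mask, flair, quantile: float = 0.5):
    """Partition a WMH mask into intense / less-intense halves by FLAIR level.

    Voxels strictly above the within-mask intensity quantile are "intense";
    ties (including a uniform mask) fall to "less intense".  Returns
    ``(intense_mask, less_intense_mask)`` — disjoint, union = ``wmh_mask``.
    """
    wmh_mask = np.asarray(wmh_mask, bool)
    flair = np.asarray(flair, dtype=float)
    if flair.shape != wmh_mask.shape:
        raise ValueError("flair and wmh_mask must share one grid")
    if not 0 <= quantile <= 1:
        raise ValueError("quantile must be in [0, 1]")
    if not wmh_mask.any():
        log.warning("split_wmh_intensity: empty WMH mask")
        return np.zeros_like(wmh_mask), np.zeros_like(wmh_mask)
    thr = np.quantile(flair[wmh_mask], quantile)
    intense = wmh_mask & (flair > thr)
    less = wmh_mask & ~intense
    return intense, less


@dataclass
class ContourLabels:
    """Contour ring labelling of NAWM around the WMH edge."""

    labels: np.ndarray           # int16, codes from `labels` module
    n_contours: int
    width_voxels: int
    connectivity: int

    def contour_mask(self, k: int) -> np.ndarray:
        return self.labels == L.contour_label(k)

    @property
    def distant_mask(self) -> np.ndarray:
        return self.labels == L.NAWM

    def counts(self) -> dict[str, int]:
        out = {L.contour_name(k): int(np.count_nonzero(self.contour_mask(k)))
               for k in range(1, self.n_contours + 1)}
        out["distant_nawm"] = int(np.count_nonzero(self.distant_mask))
        return out


def geodesic_distance_voxels(seed_mask, domain_mask,
                             connectivity: int = 6) -> np.ndarray:
    """Geodesic voxel-step distance from ``seed_mask`` through
    ``domain_mask``, by iterated dilation restricted to the domain.

    Unreachable domain voxels get +inf; seed voxels 0.
    """
    seed = np.asarray(seed_mask, bool)
    domain = np.asarray(domain_mask, bool)
    if seed.shape != domain.shape:
        raise ValueError("masks must share one grid")
    st = _structure(connectivity)
    dist = np.full(seed.shape, np.inf)
    dist[seed] = 0.0
    frontier = seed.copy()
    reached = seed | ~domain  # never step outside the domain
    step = 0
    while frontier.any():
        step += 1
        frontier = ndimage.binary_dilation(frontier, st) & ~reached & domain
        dist[frontier] = step
        reached |= frontier
    return dist


def make_contours(wmh_mask, nawm_mask, n_contours: int = 10,
                  width_voxels: int = 2,
                  connectivity: int = 6) -> ContourLabels:
    """Build ``n_contours`` rings of ``width_voxels`` around the WMH edge.

    An empty WMH mask labels all NAWM distant (a patient with no visible
    hyperintensities) with a warning rather than an error.
    """
    wmh = np.asarray(wmh_mask, bool)
    nawm = np.asarray(nawm_mask, bool)
    if wmh.shape != nawm.shape:
        raise ValueError("wmh_mask and nawm_mask must share one grid")
    if n_contours < 1 or width_voxels < 1:
        raise ValueError("n_contours and width_voxels must be >= 1")

    out = np.zeros(wmh.shape, dtype=np.int16)
    nawm_only = nawm & ~wmh
    out[nawm_only] = L.NAWM
    if not wmh.any():
        log.warning("make_contours: empty WMH mask; all NAWM labelled distant")
        return ContourLabels(out, n_contours, width_voxels, connectivity)

    dist = geodesic_distance_voxels(wmh, nawm_only | wmh, connectivity)
    for k in range(1, n_contours + 1):
        ring = nawm_only & (dist > (k - 1) * width_voxels) \
            & (dist <= k * width_voxels)
        out[ring] = L.contour_label(k)
    return ContourLabels(out, n_contours, width_voxels, connectivity)
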