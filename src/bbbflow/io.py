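"""NIfTI / bval-bvec / CSV I/O and run manifests.

Conventions: voxel indices are 0-based; all volumes of one patient share a
grid and affine, and an affine mismatch is an error (registration is out of
scope, never a silent resample).  No function mutates its input files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def affine_from_voxel_size(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def write_volume(path, data, affine=None, voxel_size_mm=(1.0, 1.0, 1.0)):
    """Write an array as NIfTI-1; affine defaults to the voxel-size scaling."""
    if affine is None:
        affine = affine_from_voxel_size(voxel_size_mm)
    img = nib.Nifti1Image(np.asarray(data), affine)
    nib.save(img, str(path))
    return Path(path)


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (array, affine)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with the filename
        raise IOError(f"cannot read NIfTI {path}: {exc}") from exc
    return np.asarray(img.dataobj), img.affine


def check_same_geometry(affines: dict, atol: float = 1e-6) -> None:
    items = list(affines.items())
    ref_name, ref = items[0]
    for name, aff in items[1:]:
        if not np.allclose(aff, ref, atol=atol):
            raise ValueError(f"affine mismatch between {ref_name} and {name}; "
                             "inputs must be co-registered on one grid")


def write_bvals_bvecs(prefix, bvals, bvecs):
    """FSL-style text files: one row of b-values; three rows of components."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".bval"), np.atleast_2d(bvals), fmt="%.6g")
    g = np.asarray(bvecs, dtype=float)
    if g.shape[1] == 3:
        g = g.T
    np.savetxt(prefix.with_suffix(".bvec"), g, fmt="%.8g")


def read_bvals_bvecs(bval_path, bvec_path):
    try:
        bvals = np.loadtxt(bval_path).ravel()
        bvecs = np.loadtxt(bvec_path)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot parse {bval_path} / {bvec_path}: {exc}") from exc
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise IOError(f"{bvec_path}: shape {bvecs.shape} does not pair with "
                      f"{bvals.size} b-values")
    return bvals, bvecs


def write_table(path, df: pd.DataFrame) -> Path:
    # 6 significant digits: plenty for x1e-3 slopes, keeps tables compact
    df.to_csv(path, index=False, float_format="%.6g")
    return Path(path)


def read_table(path, expected_columns=None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if expected_columns:
        unknown = [c for c in df.columns if c not in expected_columns]
        if unknown:
            import logging

            logging.getLogger(__name__).warning(
                "%s: unknown columns preserved: %s", path, unknown)
    return df


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, extra: dict | None = None) -> Path:
    """Checksum manifest of every file in a run directory (deterministic:
    sorted relative paths, no timestamps)."""
    out_dir = Path(out_dir)
    files = sorted(p for p in out_dir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "files": {str(p.relative_to(out_dir)): sha256_file(p) for p in files},
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
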