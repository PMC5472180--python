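"""End-to-end orchestration: simulate -> T1 map -> contours -> quantify ->
DTI -> models, producing a run directory with tables and a checksum
manifest.

The pipeline is deterministic given the config seed: every patient gets an
independent child random stream derived from (seed, patient_id).  A stage
failure halts the run with the stage name; partial outputs already written
are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from . import labels as L
from .config import CohortConfig, ConfigError
from .contours import make_contours, merge_tissues, split_wmh_intensity
from .dce import (build_slope_table, extract_enhancement, extract_vif,
                  vif_level)
from .diffusion import MD_REPORT_SCALE, compute_fa, compute_md, fit_tensor
from .relaxometry import fit_t10_vfa
from .stats import fit_cognition_model, fit_contour_gradient, \
    fit_leakage_models
from .synthetic import (Cohort, generate_cohort, simulate_cognition,
                        simulate_dce, simulate_dwi)
from .synthetic.anatomy import generate_anatomy
from .synthetic.dwi import default_gradient_scheme
from .synthetic.truth import CovariateEffects

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    out_dir: str | Path = "run"
    write_images: bool = False
    fit_models: bool = True
    n_dwi_directions: int = 12
    dwi_bval: float = 1000.0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.n_dwi_directions < 6:
            raise ConfigError("n_dwi_directions: need >= 6")


@dataclass
class PatientResult:
    labels: np.ndarray
    t10_ms: np.ndarray
    md_map: np.ndarray
    fa_map: np.ndarray
    series: list
    sinus_level: float
    t10_means: dict
    md_means: dict
    fa_means: dict


def _analysis_labels(anatomy, config: CohortConfig) -> np.ndarray:
    """Recover the fine label map from the raw masks, as the analysis of a
    real cohort would: merge, split WMH by FLAIR intensity, ring the NAWM."""
    lab = merge_tissues(anatomy.csf, anatomy.nawm, anatomy.dgm, anatomy.wmh,
                        anatomy.index_infarct, anatomy.old_infarct,
                        anatomy.sinus)
    intense, _ = split_wmh_intensity(anatomy.wmh, anatomy.flair)
    lab[intense] = L.WMH_INTENSE
    cl = make_contours(anatomy.wmh, anatomy.nawm & ~anatomy.wmh,
                       config.n_contours, config.contour_width_voxels)
    ring = cl.labels > L.CONTOUR_BASE
    lab[ring] = cl.labels[ring]
    return lab


def _label_means(volume, labels, valid=None) -> dict:
    out = {}
    for code in np.unique(labels):
        if code == L.BACKGROUND:
            continue
        m = labels == code
        if valid is not None:
            m &= valid
        if m.any():
            out[L.label_name(int(code))] = float(np.nanmean(volume[m]))
    return out


def process_patient(cohort: Cohort, patient_id: int, run: RunConfig,
                    bvals, bvecs) -> PatientResult:
    """Simulate one patient's images and run the full analysis on them."""
    config = cohort.config
    rng = np.random.default_rng([config.seed, patient_id])
    cov = cohort.covariates.set_index("patient_id").loc[patient_id]

    anatomy = generate_anatomy(config, int(cov.fazekas_score),
                               bool(cov.has_old_infarct), rng)
    params = cohort.patient_params(patient_id)
    truth_lab = anatomy.truth_labels(config.n_contours,
                                     config.contour_width_voxels)
    dce, pre = simulate_dce(truth_lab, params, config, rng)
    noise_sd = 0.0
    if config.snr > 0 and config.noise_model != "none":
        noise_sd = params["nawm"].m0 / config.snr * 0.05
    dwi = simulate_dwi(truth_lab, params, bvals, bvecs, noise_sd, rng)

    t1map = fit_t10_vfa(pre.low_flip, pre.high_flip, pre.flips_deg,
                        config.tr_ms)
    labels = _analysis_labels(anatomy, config)

    # pre-contrast baseline at the dynamic flip angle: the high-flip
    # pre-contrast acquisition (the dynamic sequence reuses that flip)
    baseline = pre.high_flip
    tissue_only = np.where(labels == L.SINUS, L.BACKGROUND, labels)
    series = extract_enhancement(dce.data, dce.times_min, tissue_only,
                                 baseline)
    # the tissue-level models use whole compartments: pool the WMH
    # intensity strata into "wmh" and the contour rings into "nawm"
    # (the per-ring strata stay in the table for the penumbra analyses)
    series = [s for s in series if s.label != "nawm"]
    for mask, name in ((anatomy.wmh, "wmh"), (anatomy.nawm, "nawm")):
        if mask.any():
            for s in extract_enhancement(dce.data, dce.times_min,
                                         mask.astype(np.int16), baseline):
                s.label = name
                series.append(s)
    vif = extract_vif(dce.data, dce.times_min, labels == L.SINUS, baseline)
    level = vif_level(vif)

    tensors = fit_tensor(dwi, bvals, bvecs)
    ok = tensors.valid & tensors.nonneg
    md = np.where(ok, compute_md(tensors.eigenvalues) * MD_REPORT_SCALE,
                  np.nan)
    fa = np.where(ok, compute_fa(tensors.eigenvalues), np.nan)

    t10_means = _label_means(t1map.t10_ms, labels, t1map.valid)
    md_means = _label_means(md, labels)
    fa_means = _label_means(fa, labels)
    for mask, name in ((anatomy.wmh, "wmh"), (anatomy.nawm, "nawm")):
        if mask.any():
            t10_means[name] = float(np.nanmean(
                np.where(t1map.valid, t1map.t10_ms, np.nan)[mask]))
            md_means[name] = float(np.nanmean(md[mask]))
            fa_means[name] = float(np.nanmean(fa[mask]))

    return PatientResult(labels=labels, t10_ms=t1map.t10_ms, md_map=md,
                         fa_map=fa, series=series, sinus_level=level,
                         t10_means=t10_means, md_means=md_means,
                         fa_means=fa_means)


def analyze_cohort_images(cohort: Cohort, run: RunConfig) -> pd.DataFrame:
    """Image-mode analysis of every patient; returns the long slope table
    with diffusion and T1 summaries attached."""
    bvals, bvecs = default_gradient_scheme(run.n_dwi_directions, run.dwi_bval)
    per_patient, levels, t10m = {}, {}, {}
    mdm, fam = {}, {}
    for pid in cohort.covariates.patient_id:
        res = process_patient(cohort, int(pid), run, bvals, bvecs)
        per_patient[int(pid)] = res.series
        levels[int(pid)] = res.sinus_level
        for lab, v in res.t10_means.items():
            t10m[(int(pid), lab)] = v
        for lab, v in res.md_means.items():
            mdm[(int(pid), lab)] = v
        for lab, v in res.fa_means.items():
            fam[(int(pid), lab)] = v
    table = build_slope_table(per_patient, cohort.covariates, levels, t10m)
    table["md_1e9"] = [mdm.get((p, t), np.nan)
                       for p, t in zip(table.patient_id, table.tissue)]
    table["fa"] = [fam.get((p, t), np.nan)
                   for p, t in zip(table.patient_id, table.tissue)]
    return table


def run_pipeline(run: RunConfig,
                 effects: CovariateEffects | None = None) -> dict:
    """Simulate-then-analyze a full cohort into ``run.out_dir``.

    Returns a dict of the in-memory artifacts; on disk: the serialized
    config, covariate and slope tables, model coefficient tables, and a
    checksum manifest (plus per-patient volumes if ``write_images``).
    """
    run.validate()
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = run.cohort
    effects = CovariateEffects.reference() if effects is None else effects
    artifacts: dict = {}

    def stage(name, fn, *args, **kwargs):
        log.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(name, exc) from exc

    config.to_yaml(out / "config.yaml")
    cohort = stage("simulate", generate_cohort, config, effects)
    cov = stage("cognition", simulate_cognition, cohort)
    bio.write_table(out / "covariates.csv", cov)
    artifacts["cohort"] = cohort

    table = stage("analyze", analyze_cohort_images, cohort, run)
    bio.write_table(out / "slope_table.csv", table)
    artifacts["slope_table"] = table

    if run.write_images:
        stage("write_images", _write_patient_images, cohort, run, out)

    if run.fit_models:
        artifacts["coefficients"] = stage(
            "fit_leakage", fit_leakage_models, table)
        bio.write_table(out / "leakage_coefficients.csv",
                        artifacts["coefficients"])
        k = table.tissue.str.extract(r"contour_(\d+)")[0].dropna().nunique()
        if k >= 3:
            artifacts["contour_gradient"] = stage(
                "fit_contour_gradient", fit_contour_gradient, table,
                n_contours=config.n_contours)
            bio.write_table(out / "contour_gradient.csv",
                            artifacts["contour_gradient"])
        wmh_obs = (table[table.tissue == "wmh"]
                   [["patient_id", "slope_1e3"]]
                   .rename(columns={"slope_1e3": "wmh_slope_1e3"}))
        cog_df = cov.merge(wmh_obs, on="patient_id", how="left")
        if cog_df.dropna(subset=["acer_1yr", "wmh_slope_1e3"]).shape[0] >= 20:
            artifacts["cognition_model"] = stage(
                "fit_cognition", fit_cognition_model, cog_df,
                include_baseline_acer=True)
            bio.write_table(out / "cognition_model.csv",
                            artifacts["cognition_model"])

    artifacts["manifest"] = bio.write_manifest(
        out, extra={"seed": config.seed, "n_patients": config.n_patients})
    return artifacts


def _write_patient_images(cohort: Cohort, run: RunConfig, out: Path) -> None:
    bvals, bvecs = default_gradient_scheme(run.n_dwi_directions, run.dwi_bval)
    config = cohort.config
    for pid in cohort.covariates.patient_id:
        pid = int(pid)
        rng = np.random.default_rng([config.seed, pid])
        cov = cohort.covariates.set_index("patient_id").loc[pid]
        anatomy = generate_anatomy(config, int(cov.fazekas_score),
                                   bool(cov.has_old_infarct), rng)
        params = cohort.patient_params(pid)
        truth_lab = anatomy.truth_labels(config.n_contours,
                                         config.contour_width_voxels)
        dce, pre = simulate_dce(truth_lab, params, config, rng)
        dwi = simulate_dwi(truth_lab, params, bvals, bvecs, 0.0, rng)
        pdir = out / f"patient_{pid:03d}"
        pdir.mkdir(exist_ok=True)
        vx = config.voxel_size_mm
        bio.write_volume(pdir / "dce.nii", dce.data.astype(np.float32),
                         voxel_size_mm=vx)
        bio.write_volume(pdir / "precontrast_low_flip.nii",
                         pre.low_flip.astype(np.float32), voxel_size_mm=vx)
        bio.write_volume(pdir / "precontrast_high_flip.nii",
                         pre.high_flip.astype(np.float32), voxel_size_mm=vx)
        bio.write_volume(pdir / "dwi.nii", dwi.astype(np.float32),
                         voxel_size_mm=vx)
        bio.write_volume(pdir / "labels.nii", truth_lab.astype(np.int16),
                         voxel_size_mm=vx)
        bio.write_volume(pdir / "flair.nii",
                         anatomy.flair.astype(np.float32), voxel_size_mm=vx)
        bio.write_bvals_bvecs(pdir / "dwi", bvals, bvecs)
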