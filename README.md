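# bbbflow

Tissue-specific blood-brain-barrier (BBB) leakage analysis for slow
dynamic contrast-enhanced (DCE) MRI in cerebral small vessel disease, with
a synthetic cohort simulator for end-to-end validation.

In small vessel disease the BBB leaks *subtly*: after a gadolinium bolus,
white matter signal keeps creeping upward for tens of minutes while the
blood pool declines. At these permeabilities, pharmacokinetic constants
(Ktrans, v_p) are hostage to capillary-density assumptions, so `bbbflow`
instead quantifies leakage as the late **enhancement slope** per tissue,

    e(t) = (S(t) − S_pre) / S_pre,      leakage = d e / dt   (× 10⁻³ /min),

and models slopes across patients with linear mixed models. The package is
aimed at imaging scientists studying white matter hyperintensities (WMH),
their normal-appearing white matter (NAWM) penumbra, and the link between
BBB leakage and cognition after stroke.

What it provides:

* **Relaxometry** — exact two-point variable-flip-angle T1₀/M0 mapping
  from SPGR volumes (flips 2°/12°), `S = M0 sin α (1−E1)/(1−cos α E1)`.
* **Spatial scaffold** — precedence-merged tissue labels, a WMH
  intense/less-intense intensity split, and 10 concentric contours of two
  voxels' width grown geodesically from the WMH edge through NAWM.
* **DCE quantification** — per-tissue enhancement curves, OLS slopes, and
  the sagittal-sinus blood-pool reference used as a model covariate.
* **Diffusion** — log-linear tensor fit, MD (×10⁻⁹ m²/s) and FA maps.
* **Statistics** — mixed models of slopes (tissue × covariate effects,
  the per-contour leakage gradient, age-adjusted WMH-burden profiles) and
  the 1-year ACE-R cognition models with a leakage × stroke-subtype
  interaction.
* **Synthetic cohort** — Patlak + SPGR forward simulation (images and
  region-level curves), diffusion tensors hitting target MD/FA exactly,
  covariates and cognition with known ground truth at literature-scale
  effect sizes.

## Worked example

```python
from bbbflow.config import CohortConfig
from bbbflow.pipeline import RunConfig, run_pipeline

art = run_pipeline(RunConfig(cohort=CohortConfig(n_patients=30, seed=2),
                             out_dir="run"))
print(art["slope_table"].groupby("tissue").slope_1e3.mean().round(3))
```

prints the mean measured leakage slope per tissue (×10⁻³/min):

```
tissue
contour_1           0.670
...
csf                 2.460
dgm                 0.595
index_infarct       2.660
nawm                0.662
old_infarct         1.997
wmh                 1.341
wmh_intense         1.412
wmh_less_intense    1.271
```

— infarcts and CSF enhance most, WMH sits above NAWM, the intense WMH core
above the less-intense shell, and the contour slopes decay with distance
from the WMH edge, matching the generating truth. `run/` then contains the
slope table, per-tissue coefficient tables (β × 10³ with 95% CIs), the
contour-gradient fit, the cognition model and a checksum manifest.

The same stages are scriptable from the shell:

```bash
bbbflow simulate --out cohort/                 # write a synthetic cohort
bbbflow t1map --low pre2.nii --high pre12.nii --tr 8 --out maps
bbbflow contours --wmh wmh.nii --nawm nawm.nii --rings 10 --width 2 --out rings.nii
bbbflow quantify --dce dce.nii --labels rings.nii --baseline pre12.nii --out slopes.csv
bbbflow dti --dwi dwi.nii --bval dwi.bval --bvec dwi.bvec --out maps
bbbflow fit --slopes slopes.csv --model leakage --out coeffs.csv
bbbflow run --out run/                         # everything, one seed
```

The numbered drivers under `analysis/` (01 simulate → 05 cognition &
recovery) run the same narrative with printed findings and tables under
`results/`.

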