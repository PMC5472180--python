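# Methods

`bbbflow` quantifies subtle blood-brain-barrier (BBB) leakage from slow
dynamic contrast-enhanced (DCE) MRI the way low-permeability cohort studies
do: not by fitting pharmacokinetic constants, but by measuring the *slope*
of relative signal enhancement over a long (~24 min) acquisition per tissue
compartment, and modelling those slopes across patients. This note
documents the models, the defaults and why, the synthetic cohort the
package validates itself against, and the limits of what those validations
show.

## Leakage metric

After a gadolinium bolus, tissue with an intact BBB shows a brief
intravascular enhancement that then declines with the blood pool; tissue
with a leaky BBB keeps accumulating contrast, producing a slow, nearly
linear late rise in signal. The package's leakage measure for a tissue is
the ordinary-least-squares slope of mean relative enhancement

    e(t) = (S(t) - S_pre) / S_pre

against time over the frames after the first post-injection frame,
reported as `slope_1e3` (x 1e-3 per minute). Relative enhancement removes
equilibrium-signal and coil-gain differences; a raw-difference mode exists
(`normalize=False`). Tissue-mean-then-slope is the default (the slope of
the mean curve); a voxelwise route is available through the same estimator
for map-making. Pharmacokinetic modelling (Patlak Ktrans/vp fitting) is
deliberately *not* an output: at these low permeabilities every model rests
on capillary-density assumptions that vary with age and disease. The
Patlak form lives only in the simulator and in test oracles.

The sagittal-sinus blood-pool curve is extracted as the vascular reference;
its mean post-bolus level (`sinus_level`) enters every slope model as an
adjuster rather than being subtracted — intravascular contrast is handled
as a covariate, not a correction.

A practical caveat encoded in `LATE_WINDOW_START_MIN` (6 min): while the
blood pool declines monotonically after its first-pass peak, a low-Ktrans
tissue's curve can still dip for a frame or two while the fast bolus
component washes out of its plasma volume. Monotone-rise contracts
therefore apply to the post-washout window; the slope fit itself uses all
frames after the first, where the dip only perturbs the intercept.

## T1 mapping

Pre-contrast T1 (T10) comes from two spoiled-gradient-echo volumes at flip
angles 2 and 12 degrees via the linearised variable-flip-angle relation:
S/sin a regressed on S/tan a has slope E1 = exp(-TR/T1). With exactly two
angles the system is determined, so the two-point solution is exact — a
nonlinear fit would add nothing. TR must always be supplied explicitly.
Voxels whose implied E1 falls outside (0, 1) or whose T1 leaves
[50, 10000] ms (a bracket generously containing brain tissue and CSF) are
flagged invalid and counted, never zeroed. Note that *equal* signals at the
two flips are not degenerate — they occur legitimately when the Ernst angle
lies between them. No B1 correction is applied; flip angles are taken at
face value.

## WMH penumbra contours

Normal-appearing white matter (NAWM) is subdivided into 10 concentric
rings, each 2 voxels (~2 mm) wide, growing outward from the WMH edge; NAWM
beyond ring 10 is "distant". Distance is the geodesic city-block distance
*within NAWM*, computed by iterated 6-connected dilation restricted to the
NAWM mask at every step, so rings cannot jump across CSF or grey matter
and re-enter. Choices made here where the procedure was genuinely open:

* 6-connectivity (configurable to 26) keeps "two voxels ≈ 2 mm" literal on
  ~1 mm grids;
* distance is counted in voxels, not millimetres, so anisotropic voxels
  change the physical ring width;
* restricting growth to NAWM is a modelling choice — contours are defined
  as subdivisions of NAWM, so they should not traverse other tissue;
* the WMH intense / less-intense split uses a single FLAIR-like volume
  thresholded at the within-WMH median (quantile configurable), a
  simplification of multi-sequence visual grading; ties go to
  "less intense".

Tests verify ring equality against an independent Dijkstra
shortest-path oracle on the voxel graph, and a plain distance-transform
oracle in the unobstructed case.

## Diffusion metrics

Tensors are fitted by unweighted log-linear least squares (one
pseudo-inverse for all voxels); MD = trace/3 (reported in 1e-9 m^2/s) and
FA from the standard eigenvalue formula. Voxels with non-positive signals
or negative eigenvalues are flagged and excluded from summaries rather
than clipped, keeping compartment means honest; counts are logged.
Weighted or nonlinear fitting and Rician-bias correction are out of scope
— at the simulated noise levels the log-linear fit is adequate (median MD
error ~2% at SNR 30 with 32 directions and several b0 volumes).

## Statistical models

Analyses mirror a two-level design: slopes per patient x tissue, then
linear mixed models across patients with a random patient intercept
(statsmodels `MixedLM`, REML, Wald CIs, normal-approximation p-values; no
degrees-of-freedom correction and no multiple-testing adjustment — tables
report unadjusted per-term tests).

* **Tissue-specific covariate effects.** Each interaction family — age
  (per 5 years), WMH burden (per Fazekas point, 0-6), stroke subtype
  (lacunar vs cortical; negative = lower in lacunar) — is fitted in its own
  model (`response ~ tissue + tissue:x + adjusters`), the three families
  adjusting for each other as main effects, plus blood-pool level,
  within-tissue T10 deviation (raw T10 is nearly collinear with tissue
  identity), mean arterial pressure, hypertension, pulse pressure and
  smoking. Fitting one family at a time follows the convention that
  simultaneous multi-family interaction fits are fragile; it is also why
  per-tissue residual heterogeneity (e.g. CSF slopes vary far more than
  NAWM slopes) makes the pooled-variance CIs mildly conservative for the
  quiet tissues.
* **Penumbra gradient.** On contour strata only, leakage is regressed on
  the number of one-contour steps toward the WMH edge (contour 10 -> 0,
  contour 1 -> 9), adjusted for age, Fazekas score, blood pressure,
  subtype and smoking, with a random patient intercept. Positive =
  more leakage nearer the WMH.
* **Burden-stratified profiles.** Per contour / WMH stratum,
  age-adjusted group means (OLS `value ~ group + age`, evaluated at the
  overall mean age) for leakage, MD, FA and T1, with Fazekas groups
  low 0-2, medium 3-4, high 5-6.
* **Cognition.** OLS of 1-year ACE-R on standardised WMH leakage with a
  leakage x subtype interaction, adjusted for NART, Fazekas, age and
  hypertension; adding baseline (1-3 month) ACE-R turns the leakage term
  into a predictor of one-year *change* and pools it across subtypes.
* **Direct longitudinal mode.** As a cross-check, enhancement itself can
  be modelled as `enhancement ~ tissue x time (x covariate)` with a random
  time slope per patient; the two modes must (and do) agree in sign and
  approximate magnitude on noiseless cohorts. They are not numerically
  identical — the longitudinal model linearises the whole curve including
  the washout frames.

Missing covariates are handled complete-case per model with counts logged.
A rank check runs before every fit and names the collinear terms instead
of silently dropping them.

## Synthetic cohort

Because suitable patient images are not publicly available, the package
ships a generator whose defaults encode literature-scale conditions, so
every stage can be validated by parameter recovery.

**Forward model.** Plasma concentration rises linearly to a 5 mM peak at
1 min, then decays bi-exponentially (60% with a 2-min constant — the first
pass — and 40% with a 60-min constant); tissue follows Patlak,
`C_t = Ktrans * int C_p + v_p * C_p`; the sinus carries whole-blood
concentration `(1 - Hct) C_p` with Hct 0.45. Concentration maps to signal
through the SPGR equation with relaxivity 3.6 /mM/s (gadoterate at 1.5 T),
TR 8 ms, dynamic flip 12 degrees, 20 frames at 1.2-min spacing. Noise is
Rician by default (Gaussian available for analytic tests), with SNR
defined against the pre-contrast high-flip brain signal.

**Parameterisation on the slope scale.** Effects are specified in the
units the models report (x 1e-3 enhancement per minute): per-tissue base
slopes (e.g. NAWM 0.5, intense WMH 1.2, index infarct 2.5), a linear
penumbra gradient of 0.0099 per contour step toward the WMH edge, and
per-tissue covariate effects at published magnitudes (e.g. +0.024 per
Fazekas point in NAWM, +0.059 per 5 years of age in WMH, +0.206 for
hypertension in NAWM; contours inherit NAWM effects, the WMH intensity
strata inherit pooled-WMH effects). Per-patient Ktrans is obtained by
Newton-inverting the forward model's slope map (Patlak is linear in
Ktrans; the SPGR nonlinearity is the reason a plain chord calibration is
not exact), clipped at zero — leakage cannot be negative — with clip
counts recorded. The T10/sinus-level effect fields exist but default to
zero: no defensible published magnitude-with-units was available, and the
fitted models always adjust for both regardless.

**Covariates.** Age uniform on [34, 97]; Fazekas ~ round(N(2, 1.5)) clipped
to 0-6; 46% lacunar; 65% hypertensive; MAP N(100, 12); pulse pressure
N(55, 12); 30% smokers; NART N(110, 8). Covariates are drawn independently
of each other — a deliberate simplification (real age and WMH burden are
correlated) that makes the one-family-at-a-time models estimate their
generating coefficients without cross-family confounding. Patients with
Fazekas 0 carry no WMH and hence no WMH or contour rows. A per-patient
random slope intercept (sd 0.1 x 1e-3) is shared across tissues, and
tissue T10 gets independent inter-subject variability (sd 20 ms) on top of
Fazekas-linked shifts (+8 ms, +0.02 MD, -0.008 FA per point in white
matter, encoding the water-content gradient).

**Two resolutions.** The *region mode* evaluates each homogeneous
compartment once per patient (exactly equal to the region mean, since
compartments are homogeneous) and adds Gaussian noise (sd 0.001) to the
region-mean enhancement — this is where replicate-cohort recovery
experiments run, because voxelwise rasterisation would add cost but no
statistical content. The *image mode* rasterises the same truth onto a
voxel grid (default 24^3; ellipsoidal brain with CSF rim, central WMH blob
with intense core scaling with Fazekas score, deep-grey blob, infarcts,
tubular sinus, synthetic FLAIR for the intensity split) and runs the full
image pipeline: VFA T1 fit, mask merging, intensity split, contour
growth, enhancement extraction, tensor fit. On the default grid the far
contour rings can be empty once NAWM is exhausted (legal and logged); the
designed profile cohort uses a 40^3 grid so all ten rings are populated.
DWI uses prolate axisymmetric tensors built in closed form to hit each
compartment's (MD, FA) exactly.

**Cognition.** Baseline ACE-R = 55 + 0.35 NART - 0.6 age5 + N(0, 3);
1-year ACE-R = 5 + 0.8 baseline + 0.05 NART + beta_subtype * z + N(0, 3),
truncated to [0, 100], where z is the standardised true WMH leakage and
beta defaults to -1.89 for both subtypes. Recovery experiments refit the
generating model (leakage exposure = the generator's own WMH slope);
fitting against the *measured* slope instead (the pipeline's realistic
model) attenuates the coefficient by the usual errors-in-variables factor
— a few percent at the default measurement noise — which is a property of
the estimand, not an estimator defect.

**What passing does and does not show.** The phantom has no real
neuroanatomy, no partial-volume mixing, no motion, no registration error,
no B1 inhomogeneity, and its compartments are internally homogeneous;
covariates are mutually independent. Recovery therefore demonstrates that
the estimators and models are correct and calibrated *under the generative
assumptions*, not that the pipeline is robust to the full mess of clinical
MRI. Coefficients fitted to real data would additionally absorb
measurement-error attenuation, confounding between correlated covariates,
and segmentation error.

## Validation experiments and problem sizes

The replicate-recovery experiment uses 100 cohorts of n=200 at region
resolution (the three headline coefficients must be inside their fitted
95% CIs in >= 90% of replicates); type-I error of the Fazekas tests uses
400 null cohorts of n=100 over three tissues; CI calibration of the
cognition coefficient uses 200 replicates; estimator consistency compares
RMSE at n=50 vs n=800 over 10 replicates each. Image-mode checks use 30
patients at 24^3 (end-to-end ordering, determinism) and 9 designed
patients at 40^3 (contour profiles). These sizes keep the full validation
suite in the minutes range while leaving the binomial pass margins wide.

## Known limitations

* Two flip angles only; no multi-flip VFA, no inversion-recovery T1.
* The contour definition is global to the WMH set (no per-lesion rings).
* `MixedLM` assumes homoscedastic residuals across tissues; the observed
  consequence (slightly conservative CIs for low-variance tissues) is
  documented above.
* The exact mixed-model specification used in the motivating cohort
  studies (SAS, appendix-level detail) is not reproduced; the two provided
  modes bracket reasonable readings, and no numeric identity with
  published coefficient tables is claimed — they are used as generating
  truth for recovery, not as comparison targets.
* The blood-pool curve form (linear upslope + bi-exponential decay) is an
  assumption; only its qualitative shape is constrained by observation.
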