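# Methods

This note documents the models, algorithms and numerical choices behind
glomkit: what each stage assumes, which parameters matter, what the
synthetic data do and do not emulate, and where genuinely open design
choices were settled.

## Problem setting

On a 2-D H&E section through a kidney, glomeruli appear as round-to-oval
capillary tufts inside a pale Bowman capsule, confined to the cortex; the
medulla carries tubules and no glomeruli. The quantities of interest are
the glomerular density GD = n/A (profiles per mm² of cortex), mean profile
area Ā and perimeter, the mean glomerular volume via the Weibel-Gomez
stereological estimator

GV = (1.382 · Ā^{3/2}) / 1.01  (mm³, with Ā converted from µm²),

where 1.382 is the shape coefficient for spheres and 1.01 a size-
distribution correction, and the volumetric glomerular density

VGD = (1/1.382) · √((n/A)³ / (S/A))  (mm⁻³),

with S the summed profile area. Evaluating GV at Ā = S/n yields the exact
identity VGD · GV = (S/A)/1.01 — the areal fraction recovered up to the
distribution correction — which the test suite enforces to 1e-12 relative
error. Note that VGD evaluated at cohort-mean arguments (n/A ≈ 2.23 mm⁻²,
S/A ≈ 0.054) is ≈ 10.4 mm⁻³; published cohort VGD values on comparable
material are roughly 1.8× larger, which is consistent with per-individual
evaluation plus variance effects or an unstated variant of the estimator.
glomkit implements the equation exactly as written above and averages
per-individual values; it does not attempt to reconcile that gap. For the
same Jensen-inequality reason, cohort mean GV is computed as the mean of
per-individual GVs (GV of the cohort-mean area would be smaller).

## Detector chain

Commercial assisted-counting tools use a trained CNN for the three
classification stages. A desk-scale, deterministic substitute is used here,
exposed behind the same interface so a learned model could be swapped in:

1. **Tissue vs. background.** After Gaussian smoothing at 4 µm, background
   is low-saturation (< 0.02) and bright (> 0.88 of full scale) — H&E
   leaves glass nearly white while every stained structure carries eosin
   saturation. Holes below 1,000 µm² (tubule lumina, Bowman spaces) are
   filled; isolated specks below 2,500 µm² removed.
2. **Cortex vs. medulla.** Stain density (1 − brightness) is smoothed at
   20 µm by *normalized convolution over the tissue mask* — ordinary
   smoothing lets the white glass dilute boundary values and mislabels the
   outer cortical rim. The Otsu split of the smoothed density separates
   darker cortex from paler medulla. Two guards make the rule safe on
   degenerate slides: (a) if the two Otsu classes differ by less than 25%
   relative contrast the slide is treated as a single region; (b) the
   low-density class is accepted as medulla only if it carries the
   medulla's pale-lumen texture (≥ 10% of its pixels paler than 0.35 × the
   median tissue density). A single-region slide is then called medulla
   when its pale fraction is high, else cortex. Morphological
   opening/closing (6 µm radius) smooths the boundary, and medulla
   fragments below 0.05 mm² are reabsorbed into cortex.
3. **Glomerulus detection.** Inside the cortex, candidate pixels exceed
   1.35 × the median cortical stain density after 2 µm smoothing (the tuft
   is markedly darker than stroma; the pale capsule is recovered by hole
   filling). 8-connected components below the 40 µm² detection floor are
   discarded; survivors get an area (pixel count × mpp²), a Crofton
   perimeter (4 directions), a border flag, and an `outside_cortex` flag if
   the centroid leaves the cortex. A separate cleaning pass excludes
   objects with area strictly below 10,000 µm² (exactly 10,000 µm² is
   kept); border-touching objects are kept but flagged. Partly sclerotic
   glomeruli are not modeled or classified.

All density thresholds are *relative* (multiples of per-slide medians), so
the chain is invariant to a global staining-intensity factor; measured GD
varies by < 1% across the four synthetic stain levels. There is no
randomness anywhere in the chain. Slides finer than the 2 µm/px working
resolution are downsampled (anti-aliased) before analysis; upsampling
coarser material is refused.

Known biases, measured on synthetic truth: the tissue mask over-extends by
~1.4% of cortex area (the saturation boundary sits slightly outside the
rendered edge), giving a ~−1.3% bias on GD; threshold placement erodes
detected tuft areas by ~1.5–2%. Both sit well inside the 5% recovery bands
the tests enforce and are stable across resolutions (1 vs. 2 µm/px: counts
within 2%, areas within 3%) and stain levels.

## Synthetic slides

Slide geometry is defined analytically in physical µm coordinates and only
rasterized at the requested resolution: the tissue outline and the
cortex/medulla boundary are ellipses modulated by truncated Fourier radial
profiles (harmonics 2–6, amplitude SD 0.02), and the medulla scale is
solved in closed form from the profile integrals so the cortex fraction is
met exactly. The same seed therefore produces the identical physical ground
truth at any µm/px — the property that makes cross-resolution tests of the
detector meaningful.

Planted glomeruli are ellipses (axis ratio uniform in [0.75, 1], area drawn
from a normal with symmetric ±2.5 SD truncation so the mean is exact;
default 24,000 ± 4,000 µm², matching reported autopsy-cohort scales) with
count = round(target_gd × analytic cortex area). Placement is rejection
sampling with minimum center spacing of 1.5 × the mean tuft diameter
(glomeruli do not touch), a 1,000-retry budget per glomerulus (exceeding it
raises "density infeasible for geometry"), and a clearance from the cortex
boundary of the semi-major axis + the 8 µm Bowman rim + 30 µm. The extra
30 µm emulates the subcapsular/juxtamedullary glomerulus-free zone and
keeps segmentation-boundary error from clipping planted tufts. Rendering
paints a fixed palette (background, cortex stroma, paler medulla with
elongated tubule-lumen streaks, dark tuft, pale Bowman rim), scales every
color's deviation from white by one of four staining factors (0.55, 0.80,
1.00, 1.25 for very low/low/high/very high), and adds Gaussian pixel noise
(SD 2.5 of 255).

What the generator does **not** emulate: nuclei and capillary substructure,
sclerotic or partly sclerotic glomeruli, stain hue variation (only
intensity varies), blur/focus artifacts, tissue folds and cracks, and
vascular poles. Passing recovery tests therefore demonstrate correctness of
the measurement chain on well-formed material at known truth, not detector
robustness to real-world histology artifacts — the honest claim a classical
substitute for a trained model can make.

## Synthetic cohorts and eligibility

Cohort covariates are drawn per sex from published forensic-autopsy summary
statistics (54 men, 32 women by default): age, height and weight as
truncated normals on their reported (min, max) ranges, kidney weight and
length as normals, smoker/blood-alcohol/chronic-alcohol as Bernoulli at the
reported proportions. BMI is computed from height and weight; BSA uses
Du Bois (0.007184 · h^0.725 · w^0.425), the most common formula in European
clinical studies. Covariates are drawn independently — the joint
distribution is not published — so cross-covariate correlations are absent
unless a test plants them explicitly. Because ranges are asymmetric,
truncation shifts means slightly (e.g. male height mean ≈ 178.76 vs. the
nominal 178.4 cm); recovery tests compare against the truncated
distribution's own moments. The reported kidney-weight dispersions
(±5.5/±4.6 g) are used as drawn SDs as stated, though they are plausibly
standard errors; no result here depends on kidney-weight dispersion.

Each subject carries a true GD ~ N(2.23, 0.52²) truncated to the observed
per-individual range [1.29, 3.51] per mm², perturbed per side by
N(0, 0.15²) to reproduce small left/right differences, and a per-subject
mean glomerular area drawn per sex (24,750/23,641 ± 4,500 µm²).

The eligibility filter includes a record iff no exclusion flag is set and
age ≥ 18, attributing exclusions to the first triggered flag in a fixed
documented order (kidney disease, trauma, putrefaction, drug toxicity,
blood depletion, minor, mutilated). The screening-population helper plants
1,079 flagged records among 86 eligible ones to reproduce the published
inclusion flow (1,165 → 86); the per-reason split is this package's own
choice, as only the totals are published.

## Statistics

- **Normality gate:** Shapiro-Wilk p ≥ 0.05 AND |skewness| < 1, combined
  conjunctively (how the two diagnostics are merged is a documented choice);
  constant vectors are degenerate and never normal. Monte-Carlo behaviour:
  ≥ 93% acceptance for N(0,1) samples of 500, ≥ 99% rejection for
  log-normal σ = 1.
- **Group comparison:** Welch's t (unequal variances; the robust default
  when group sizes differ, 54 vs. 32) when both groups pass the gate, else
  Wilcoxon-Mann-Whitney. Measured type-I error at the cohort's group sizes
  is within [0.04, 0.06] over 10,000 null replicates.
- **Chi-squared:** Pearson, no Yates correction.
- **Median split:** low = values ≤ median, high = values > median (ties to
  the low group; the published group headers use strict inequalities and
  are silent on ties); optional within-sex stratification re-computes the
  median per sex.
- **Regression strategy:** univariate OLS per covariate; covariates with
  p < 0.05 enter one multivariable model; if the full model's residuals
  fail Shapiro-Wilk (p < 0.05) and the outcome is strictly positive, the
  outcome is log-transformed and the full model refit. Collinearity
  (condition number of the standardized design > 1e3) raises an error
  naming the most correlated pair. 95% CIs throughout; no multiple-testing
  correction, matching the analysis plan being reproduced.
- **Median CI:** distribution-free binomial order-statistic interval at
  95% (the published CI does not name a method).

## Problem sizes and numerical choices

Default synthetic slides are 1200 × 1200 px at 2 µm/px (2.4 × 2.4 mm,
≈ 2.7 mm² cortex, ≈ 6 glomeruli at GD 2.23) — large enough that each slide
carries a meaningful cortex/medulla boundary and several glomeruli, small
enough that recovery experiments over dozens of slides and
10,000-replicate calibration runs complete in minutes on one CPU.
Batch experiments (20 slides for density/size recovery, 10,000 null
replicates for test size, 1,000 replicates for CI coverage, 4 stain levels
on one geometry) are seeded from a single SeedSequence; identical
configuration and seed reproduce byte-identical metric CSVs, and the run
manifest stores SHA-256 hashes of every artifact.

Degenerate inputs are handled explicitly: empty slides yield GD 0 with NaN
size statistics (never 0, which would corrupt cohort means); glomeruli
with zero measurable cortex raise; an all-medulla slide yields cortex area
0 and an empty detection list; single-kidney individuals are aggregated
from the available side and flagged.

## Limitations

The detector is a fixed classical operator chain tuned to H&E-like
contrast; it is a stand-in for a trained model, not a competitor on real
slides. Stereological estimators assume spherical, non-touching particles
and unbiased 2-D sampling; GD is a proxy for nephron endowment, not a
nephron count — converting to glomeruli per kidney would require cortical
volume, which is out of scope. Cohort-level statistical results on
synthetic cohorts inherit the generator's independence assumptions and
cannot validate findings on real populations.
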