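# glomkit

Glomerular morphometry from H&E-stained kidney section images, built for
autopsy-scale material: whole-section samples containing hundreds of
glomeruli per slide, where manual counting is impractical.

The package provides, as a tested and reusable pipeline:

- **segmentation** — a deterministic three-stage classical detector:
  background vs. tissue, cortex vs. medulla, then glomerulus candidates
  inside the cortex, with a 40 µm² detection-time minimum object size and a
  post-hoc cleaning filter that excludes objects below 10,000 µm²;
- **morphometry** — glomerular density GD = n/A (glomeruli per mm² of
  cortex), mean cross-sectional area and perimeter, mean glomerular volume
  by the Weibel-Gomez estimator GV = (1.382 · Ā^{3/2})/1.01, and volumetric
  glomerular density VGD = (1/1.382)·√((n/A)³/(S/A)), with per-kidney and
  per-individual aggregation;
- **validation** — one-to-one matching of detections against reference
  counts with false-positive/false-negative rates relative to the reference;
- **cohort statistics** — normality-gated two-group comparisons (Welch t or
  Wilcoxon-Mann-Whitney), chi-squared tests, Pearson/Spearman correlation,
  median split, and a univariate-screen → fully-adjusted OLS regression
  strategy with a log-transform fallback;
- **synthetic data** — a generator of labeled H&E-like slides (cortical band
  with planted elliptical glomeruli, glomerulus-free medulla, four staining
  intensities) and autopsy-style cohorts with known ground truth, since real
  forensic material cannot be redistributed.

## Worked example

```python
from glomkit import SlideSpec, generate_slide, process_slide
from glomkit.validation import match_objects, error_rates

spec = SlideSpec(target_gd=2.23, area_mean=24_000.0, seed=1)  # 2 µm/px slide
image, truth = generate_slide(spec)
metrics, kept, excluded, regions = process_slide(image)
match = match_objects(kept, truth)

print(f"planted {truth.n_glomeruli} glomeruli in {truth.cortex_area_mm2:.2f} mm2 cortex")
print(f"kept {metrics.n_glomeruli}, GD {metrics.gd_per_mm2:.2f}/mm2, "
      f"mean area {metrics.mean_area_um2:.0f} um2, GV {metrics.gv_mm3:.4f} mm3")
print(f"FP {match.n_false_positive}, FN {match.n_false_negative}")
```

prints

```
planted 6 glomeruli in 2.68 mm2 cortex
kept 6, GD 2.21/mm2, mean area 25368 um2, GV 0.0055 mm3
FP 0, FN 0
```

i.e. every planted glomerulus was recovered, the density estimate 2.21/mm²
sits within ~1% of the planted truth (6 / 2.68 mm² ≈ 2.24), and the mean
profile area of ~25,400 µm² gives a Weibel-Gomez volume of 0.0055 mm³.

A whole synthetic cohort (two kidneys per subject, metrics, validation and
statistics reports, manifest and log) runs from the shell:

```bash
glomkit run --out my_run --n-male 54 --n-female 32 --seed 1
```

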