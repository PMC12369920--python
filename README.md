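# shgquant

Quantification of two-channel second-harmonic-generation (SHG) collagen
imaging for tumor-microenvironment studies: the forward/backward
scattering ratio (**F/B**), collagen **fiber-angle variability (FAV)**,
seeded synthetic phantoms with known ground truth, and the
repeated-measures statistics used to compare these metrics across
patient groups.

## Who this is for

SHG microscopy gives label-free contrast for fibrillar collagen. Two
image-derived quantities are prognostic of metastatic outcome in breast
and colon carcinoma: the ratio of forward- to backward-scattered SHG
intensity (sensitive to fibril diameter, spacing and packing disorder)
and the dispersion of fiber orientations (lower dispersion = more
organized stroma). This package is for imaging groups who acquire
paired F/B z-stacks of FFPE H&E sections — three fields of view in the
cellular tumor bulk (TB) and three in the collagenous tumor–stroma
interface (TSI) per sample — and need a reproducible pipeline from raw
TIFFs to per-patient metrics and cohort-level statistics.

## The metrics

**F/B.** Each channel's 3-slice z-stack is maximum-intensity projected
and background-subtracted. Collagen pixels are segmented by a
progressive-window adaptive threshold: a global seed binarization at
0.6× the image mean, then, per pixel, a series of progressively smaller
windows centered on the pixel; the smallest window whose fraction of
seed pixels exceeds 5% supplies the local threshold, and the pixel is
kept iff its intensity strictly exceeds the mean within that window.
The F and B masks are multiplied, the masked per-pixel ratio image
F(x)/B(x) is formed, and

&nbsp;&nbsp;&nbsp;&nbsp;F/B = mean of the strictly positive finite pixels of the masked ratio image.

**FAV.** Fibers are detected in the F image (ridge enhancement at the
expected fiber width via the smoothed-Hessian tubeness filter,
hysteresis thresholding, skeletonization, branch splitting with
collinear re-merging, per-segment orientation by principal axis) and

&nbsp;&nbsp;&nbsp;&nbsp;FAV = sample standard deviation (n−1) of the axial fiber angles in [0°, 180°).

A wrap-robust axial circular SD (doubled-angle resultant) is available
as `circular_fav` for sensitivity analysis.

**Cohort statistics.** Unadjusted group comparisons use Mann-Whitney U
(continuous) and Pearson chi-squared without continuity correction
(categorical) on per-patient means; the repeated ROI measurements are
modelled with a linear mixed model, `value ~ factor + (1 | patient)`,
fitted by REML (`RandomInterceptModel.from_dataframe(...).fit()`).

## Worked example

No patient images are distributed, so the example runs on a synthetic
phantom whose ground truth is known by construction:

```python
import numpy as np
from shgquant import (PhantomConfig, generate_phantom, fb_pipeline,
                      detect_fibers, compute_fav, max_project,
                      subtract_background)

cfg = PhantomConfig(shape=(256, 256), n_fibers=20, fiber_width_px=3,
                    fiber_length_range_px=(50, 120), true_fb=16.0,
                    angle_sd_deg=15.0, seed=42)
stack, truth = generate_phantom(cfg)

res = fb_pipeline(stack, background_method="constant",
                  background_f=cfg.background_f, background_b=cfg.background_b)
print(f"F/B = {res.fb_value:.2f} over {res.n_pixels} pixels")

pair = subtract_background(max_project(stack), "constant",
                           cfg.background_f, cfg.background_b)
fav = compute_fav(detect_fibers(pair.f_img, scale_px=3, min_length_px=20))
print(f"FAV = {fav.fav_deg:.2f} deg from {fav.n_fibers} fibers")
```

prints

```
F/B = 15.87 over 7767 pixels
FAV = 13.32 deg from 27 fibers
```

The recovered F/B (15.87) is within 1% of the phantom's true uniform
ratio 16; the FAV (13.32°) estimates the dispersion of the angles the
generator actually drew (12.01° realized for a configured generative SD
of 15° — with only 20 fibers the realized sample SD itself fluctuates).

## Command line

```bash
shgquant simulate phantom --seed 3 --out-dir ph/      # F/B TIFFs + truth JSON
shgquant compute-fb  --f ph/F.tif --b ph/B.tif --bg-f 200 --bg-b 200 --out fb.csv
shgquant compute-fav --f ph/F.tif --out fav.csv
shgquant simulate cohort --seed 1 --out cohort.csv    # + cohort_patients.csv
shgquant cohort-stats --measurements cohort.csv --patients cohort_patients.csv --out report.json
shgquant run --manifest manifest.csv --out-dir out/ [--covariates cov.csv] [--qc]
```

`run` executes the full read → project → subtract → mask → F/B and
detect → FAV → aggregate → statistics chain over a manifest CSV
(`patient_id, region_label, roi_index, f_path, b_path`) and writes
metric CSVs, an optional cohort report, QC panels and a provenance JSON
recording every parameter.

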