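# Methods

This note documents the models, algorithms and numerical choices behind
`shgquant`, in the spirit of the methods documentation of statistical
and simulation packages: what is computed, under which assumptions,
which knobs matter, and what the synthetic validation does and does not
demonstrate.

## Image model

A field of view is a pair of co-registered intensity stacks
`(slices, rows, cols)`: the forward-scattered SHG channel F and the
backward-scattered channel B, typically three 512×512 slices at a 2 µm
z-step. Each channel is reduced by maximum-intensity projection (a
per-pixel autofocus surrogate when the section is tilted relative to
the focal plane) and a per-channel scalar background offset is
subtracted with clipping at zero. The offset is supplied as a constant
(e.g. from an off-specimen measurement) or estimated as the mean of the
pixels at or below the 5th intensity percentile of the projection
("offscene-mean"); neither claims to reproduce any particular
instrument's dark-signal calibration, and the method and values used
are always recorded in the output provenance. No flat-field or PSF
correction, registration, or glass-reflection unmixing is applied.

## Progressive-window adaptive masking and F/B

Collagen-pixel segmentation is a two-stage threshold per channel:

1. **Seed:** pixel ∈ seed iff intensity > `global_factor` × image mean
   (`global_factor` = 0.6, dimensionless).
2. **Adaptive pass:** for each pixel, windows from a strictly
   decreasing schedule of odd side lengths are centered on it and
   clipped at the image borders. Among the windows whose fraction of
   seed pixels strictly exceeds `min_fill_fraction` (= 0.05), the
   *smallest* is selected; the output pixel is 1 iff its intensity
   strictly exceeds the mean intensity over that window. If no window
   qualifies the pixel is background (`nodata_policy="background"`,
   default); thresholding against the largest window is available for
   sensitivity analysis.

The default schedule halves from the largest odd size that fits the
image down to 3 (512×512 → 511, 255, 127, 63, 31, 15, 7, 3), spanning
all scales at logarithmic cost; it is configurable and recorded in
provenance. Both thresholds use strict `>`. Windows are clipped, not
padded, and fill fractions are computed over the clipped area.

The F and B masks are multiplied; on the combined mask the per-pixel
ratio F/B is formed (pixels with B ≤ 0 after background subtraction are
excluded — a mean over nonzero ratio pixels is only defined for finite
ratios) and the F/B metric is the mean of the strictly positive finite
ratio pixels, with the contributing pixel count reported. An empty
contributing set raises an explicit error rather than returning NaN.

**Implementation and its oracle.** The production implementation uses
integral images: one pass per window size, with border clipping
expressed through index clamping. A naive per-pixel double-loop
reference (`adaptive_window_threshold_naive`) is kept in the package as
the executable definition. Both compare `pixel × window_area >
window_sum` in float64 — no division — so for integer-valued data
(every sum being exact in float64) the two paths are *bit-identical*;
the test suite and the acceptance script verify this on 100+ random
images across schedules and both no-data policies.

**Invariances.** Because both thresholds are relative to means, the
masks are invariant under positive scaling of a channel, and the F/B
value is equivariant: scaling F by c scales F/B by exactly c (the test
uses powers of two, for which floating-point scaling is exact).
Swapping proportional channels maps F/B → 1/(F/B).

## Fiber detection and FAV

FAV is the sample standard deviation (n−1 denominator) of the detected
fibers' axial angles, taken as plain reals in [0°, 180°) measured from
the image row axis. The linear SD is the reported statistic — published
FAV values range up to ~74°, above the ~52° linear SD of an axially
uniform sample, which is only reachable without circular correction —
and the angles are unweighted by fiber length or intensity. The
wrap-robust alternative (`circular_fav`: double the angles, compute the
circular SD √(−2 ln R) of the resultant length R, halve back to the
axial scale) is provided and tested for rotation invariance (±0.5°)
but never silently substituted. FAV requires ≥ 2 fibers; fewer is an
explicit insufficient-data condition.

The detector replaces curvelet-based fiber extraction with a
contract-equivalent chain: Sato tubeness filtering at σ =
`scale_px`/2, hysteresis thresholding at 0.2/0.4 of the peak ridge
response, skeletonization, iterative spur pruning (endpoint stripping,
`max(3, scale_px)` rounds — noise barbs vanish, genuine ends lose a few
pixels), splitting at remaining branch points, and a union-find merge
of segments that are axially aligned (< 15°) *and* whose endpoint gap
runs along both segment axes — so the halves of a straight fiber split
at a crossing are rejoined while parallel neighbors are not. Each
fiber's angle is the principal axis of its skeleton coordinates; fibers
shorter than `min_length_px` skeleton pixels are discarded. On
default-noise phantoms with 30 non-overlapping fibers the detector
reaches recall 1.0 with angular RMSE ≈ 0.26°; its contract in the test
suite is recall ≥ 0.9 and RMSE ≤ 3°.

## Synthetic phantoms

`generate_phantom` renders fibers as ridges with a Gaussian transverse
profile: centerline sampled at 0.5 px, optional sinusoidal bend
(`curvature` × length amplitude), profile `exp(−d²/2σ²)` with σ = 0.75
× `fiber_width_px`, truncated at 3σ. The ground-truth fiber footprint
is the core d ≤ width/2 — entirely inside the concave part of the
cross-section, so core pixels are locally brighter than any window mean
around them, mirroring the soft falloff (PSF blur, slight defocus) of
real imaged fibers; the full rendered extent is returned separately,
and "true background" means pixels with no fiber signal at all. The B
channel renders at `f_amplitude/true_fb` × profile and F at `true_fb` ×
that, so F = true_fb × B holds exactly per pixel before background and
noise; overlaps take the per-channel maximum (with per-fiber ratios,
use non-overlapping packing if exact per-pixel truth is needed). The
three slices share geometry and differ only in noise, so the projection
behaves as the autofocus surrogate it is in acquisition.

**Noise and amplitude defaults.** Shot noise is Poisson with a detector
gain: counts = intensity/`noise_scale`, image = counts ×
`noise_scale`. The defaults (`f_amplitude` 40 000, gain 0.25,
background 200) put the backward channel at several thousand photons
per core pixel even at true F/B = 25. This regime was chosen from the
estimator's error model: the mean-of-ratios estimator carries three
small-sample biases that all scale like 1/√(B-channel counts) — the
convexity of 1/B, the order statistics of max-projecting noisy slices,
and the mask's conditioning on B exceeding a local mean. At ≥ 4 000
counts each term is ≲ 1%, and the pipeline recovers true ratios in
{5, 10, 16, 25} within ~1% (median of 10 seeds; the acceptance contract
is 5%). At low photon counts these biases are real properties of the
estimator, not implementation artifacts; users working in a dim regime
should expect a downward bias of order 0.85/√counts from projection and
selection each.

**Orientation sampling.** Angles are axial wrapped-normal: draw
Normal(`angle_mean_deg`, `angle_sd_deg`), reduce mod 180 — controllable
SD for small σ and the right topology for axial data. With
non-overlapping packing, each fiber's angle and length are drawn once
and only its placement is retried on collision; retrying the angle
would selectively reject orientations far from the mean direction
(they cross more already-placed fibers) and systematically shrink the
realized angle SD — an effect of 1–3° that was measured and designed
out. Packing failure after `max_retries_per_fiber` placements raises an
error rather than degrading silently.

## Synthetic cohorts

`generate_cohort` draws a two-group patient cohort: per-ROI measurement
= group/region mean + patient random intercept (Normal, `patient_sd`,
drawn per patient per metric and shared across regions) + ROI noise
(Normal, `roi_sd`). The default design mirrors a two-region study with
3 fields of view per region and an unbalanced 77/11 group split;
covariates (age, BMI, sex, three-level tumor stage, grade, smoking) are
drawn per group from simple parametric models, with BMI missing at a
configurable rate to exercise complete-case accounting. The generator
emulates the *statistical structure* of a real cohort (hierarchical
variance, unbalanced groups, missingness), not the biology: covariates
are independent of the imaging metrics unless configured otherwise, so
passing tests demonstrate calibration and recovery of the analysis
machinery, not any biological association.

## Cohort statistics

Unadjusted comparisons operate on per-patient means (one value per
patient per region per metric, the mean over available ROIs);
continuous variables use Mann-Whitney U, categorical variables use
Pearson chi-squared without continuity correction (this convention
reproduces printed stage-count p-values exactly from the published
count table), and three or more ordered groups use Kruskal-Wallis
with tie correction. The Mann-Whitney p-value is exact (enumeration)
when the pooled sample has ≤ 16 observations and no ties, otherwise the
normal approximation with tie and continuity correction is used. BMI
classes follow the clinical convention: normal < 25, overweight
[25, 30), obese ≥ 30 kg/m².

The repeated ROI measurements are analyzed with a random-intercept
linear mixed model (REML; BFGS with L-BFGS and Powell fallbacks, and an
explicit convergence error carrying the problem size when all fail).
`RandomInterceptResults` exposes the fixed effects with standard
errors and Wald p-values and both variance components. On balanced
data the fixed-effect contrast equals the plain difference of group
means (GLS = OLS), which the tests assert; parameter recovery is
verified at 200 patients/group (effect within 3 SE, variance components
within 20%). Because the default model contains a single fixed factor,
any *other* systematic between-patient structure (e.g. a group shift
when modelling only region) is absorbed into the patient variance —
the recovery tests therefore use cohorts whose only fixed structure is
the modelled factor. No multiple-testing correction is applied; both
the rank-test and the mixed-model p-values are reported side by side
in cohort summaries, along with the aggregation rule used.

The whole-cohort means quoted alongside published figures are linked to
per-group summary rows by the sample-size-weighted mean
Σnᵢmᵢ/Σnᵢ; the shipped reference table reproduces seven of the eight
published whole-cohort means within ±0.02. The published interface-FAV
whole-cohort value of the colon cohort (39.5) is not consistent with
any weighting of its per-group rows (≈ 39.34) and is excluded from
consistency checks.

## Problem sizes for validation

Desk-scale defaults keep the full validation suite under a minute
while leaving every estimate's uncertainty well inside its contract:
F/B recovery uses 128×128 phantoms with 8 fibers (10 seeds × 4 ratio
levels); FAV recovery uses 448×448 phantoms with 80 non-overlapping
fibers (10 seeds × 3 dispersion levels — more fibers shrink the
truth-sampling noise of the realized angle SD, which dominates the
error budget at σ = 30°); calibration uses 1 000 null simulations at
n = 30/group and one 400-patient mixed-model fit. Full-scale 512×512
phantoms are the `PhantomConfig` default and run in well under a second
each.

## Known limitations

* The masking algorithm's window-scan order and exact schedule in the
  original MATLAB implementation are not public knowledge here; this
  package fixes its own documented defaults and records them in every
  output.
* The phantom imposes its F/B as ground truth; it contains no optical
  scattering physics, so agreement with phantoms says nothing about the
  physical relationship between F/B and fibril ultrastructure.
* Phantom fibers are bright, smooth and isolated compared with real
  stroma; detector performance on dense, textured, low-contrast tissue
  will be worse than the phantom contracts suggest.
* The linear FAV depends on the angular origin (it is deliberately not
  rotation invariant, matching the published definition); comparisons
  across instruments assume a consistent image orientation convention.
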