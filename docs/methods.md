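# Methods

## Scope and structure

`aohu` models threshold-based detection of calcified aortic plaque on
contrast-enhanced CT as a two-distribution problem: blood-pool
(non-plaque) pixel attenuation versus plaque pixel attenuation. Six
parts cooperate: a phantom generator (`phantom`), central-zone
measurement (`central_zone`), threshold segmentation and Agatston
scoring (`threshold`), the analytic error model (`error_model`),
cohort statistics (`cohort_stats`), and an orchestration layer
(`workbench`). Automatic aorta segmentation from real CT, centerline
fitting and vertebral-level detection are out of scope; the phantom
stands in for those upstream stages and supplies ground truth.

## Blood-pool model

Within one vessel, non-plaque pixels are Normal(μ, σ) in HU. This is
the load-bearing assumption: it turns any measured (mean, SD) AoHU pair
into a predicted fraction of the vessel exceeding a cutoff. Scan means
μ are themselves normal across a phase cohort, Normal(M, S), giving the
uniform-threshold population false-positive rate the convolution form
1 − Φ((T − M)/√(S² + σ̄²)) and making the dynamic mean + N·SD scheme
phase-invariant with FP = 1 − Φ(N).

Key parameters (units HU unless noted):

| parameter | default | provenance |
|---|---|---|
| arterial M ± S | 326 ± 68 | survey summary |
| delayed M ± S | 110 ± 16 | survey summary |
| venous M ± S | 180 ± 30 | interpolated placeholder, configurable |
| non-contrast M ± S | 40 ± 5 | placeholder, configurable |
| within-scan σ̄ | 30 | chosen mid-range of typical blood-pool noise; the per-scan SD distribution is not tabulated anywhere, so every population figure exposes and echoes the σ̄ it used |
| sex offset (F − M), arterial/venous/delayed | +65 / +22 / +20 | survey summary (upper arterial value) |
| weight slope, arterial | −2.3 per 10 kg | survey summary |
| vertebral trend | −1.5 to −4.5 per level code (codes ascend superiorly) | survey reports 1–7 HU per level moving inferiorly; applied centred per scan so the scan mean is untouched |

The phase population SD is implemented as the *residual* SD at
reference covariates (male, cohort-mean weight). With mixed
demographics the marginal spread of scan means is wider (e.g. a 50/50
sex split adds (65/2)² of variance in arterial phase); calibration
checks against 326 ± 68 therefore run on homogeneous cohorts.

## Plaque-attenuation law

Plaque pixel HU follow X = 130 + exp(Z), Z ~ Normal(ln 126, s²), with
s ≈ 0.993 solved so the untruncated 99th percentile is 1400 HU, and
samples above 1400 censored (clipped) to it. The family is a design
choice: the empirical histogram is not published numerically, only its
minimum, median and maximum, and a shifted log-normal is the simplest
right-skewed, hard-floored, two-parameter law pinned by those
summaries. Censoring rather than rejection at the cap was chosen
because it leaves the median (256 HU) and every sub-cap quantile
exactly at their calibrated values; the price is a point mass of ~1% at
1400 HU, so CDF∘quantile is the identity only below the 0.99 level.
Consequences worth knowing: FN(130) = 0, FN(250) = 48.0%, FN(median) =
50% by construction. Dynamic-scheme FN magnitudes at N = 3 (≈27% /
53% / 74% for delayed/venous/arterial under the defaults) depend on
this law's shape; only their ordering and monotonicity are robust
claims, since the true histogram is not available for recalibration.

## Phantom imaging

Scans are stacks of 2-D slices, one circular vessel per slice (radius
8–14 px at 0.7 mm spacing), background soft-tissue noise, blood pool
drawn per the hierarchy above. Lesions are wall-adjacent arcs (radial
band 0.60–0.95 of the radius, arc 30–110°) with core HU sampled i.i.d.
from the plaque law; the pre-blur support is the ground-truth mask. The
core-minus-blood delta is blurred with a Gaussian PSF (σ = 0.7 px, an
invented but typical width) before compositing, creating
partial-volume rims of intermediate attenuation both inside and just
outside the truth mask — the mechanism that makes low thresholds
recover rim pixels and high thresholds miss them. Prevalence defaults
to 0.3 scans carrying 1–3 lesions. Images are stored as integer HU
clipped to [−1024, 3071] (set `quantize=False` to keep floats).

What the phantom does *not* emulate: organ anatomy, bolus
pharmacokinetics, beam hardening, scanner spectra, motion, or any
spatial correlation of blood-pool noise. Passing tests therefore show
that the pipeline's measurement and error arithmetic are correct under
the stated statistical model, not that the model captures every
property of hospital CT.

## Central zone

"Erode to 50% of the radius" is implemented with the Euclidean distance
transform: keep pixels whose distance to the mask complement is at
least (1 − fraction)·r_eq, r_eq = √(area/π) per slice. This is exact
for disks (area ratio → fraction²), well defined for ellipses and
irregular sections, and pixel-spacing aware; iterative
structuring-element erosion was rejected as spacing-blind. Erosion is
per 2-D slice, matching per-slice measurement. SD uses the sample
convention (ddof = 1; exposed as an option — the convention is not
stated in the source material, and at the pixel counts involved the
difference is far below reporting precision). Levels outside L4–T8 are
excluded (the stricter of the two ranges the source text mentions).
Slices whose central zone touches ground-truth plaque are kept by
default; `exclude_contaminated=True` reproduces a review-style
exclusion. Degenerate slices with an empty eroded zone are dropped with
a warning.

## Segmentation and Agatston scoring

Thresholding is inclusive (HU ≥ cutoff), so a 130 HU cutoff detects a
130 HU pixel. Lesions are 8-connected components per slice with a
minimum size of 1 px (both configurable; the classical 3 mm² minimum is
available but off by default since the error analysis is pixel-based).
Agatston weights use the per-lesion, per-slice maximum HU — the
classical definition — with bins 130–199 → 1, 200–299 → 2, 300–399 → 3,
≥ 400 → 4 and score = weight × lesion area (mm²); a per-pixel-weights
variant exists for sensitivity analysis because pixel-wise wording is
also in circulation. Scores scale with pixel area, so spacing is a
required argument, and volume = plaque pixels × voxel volume when slice
thickness is supplied.

## Error model numerics

Φ and Φ⁻¹ come from `scipy.stats.norm`; no tabulated approximations.
Population averaging is scan-weighted (every scan counts equally,
regardless of vessel size) — the aggregation weights are not stated in
the source, and scan-weighting matches how per-scan statistics are
tabulated. Threshold inversion uses the closed form for parametric
populations and Brent bisection on the monotone population FP for
explicit scan lists (unreachable targets return the bracket boundary
with a warning). Monte-Carlo agreement with closed forms is asserted at
3·SE everywhere; all Monte-Carlo paths take a seeded `Generator`.

Integer pixel quantization biases empirical tail counts: for integer
threshold T the observed fraction is P(X ≥ T − 0.5), ~5% relative at
z = 3 with σ̄ = 30. Pixel-counting cross-checks therefore either average
over many scans whose thresholds have varying fractional parts (the
bias cancels to O(1/12σ²)) or compare against the continuity-corrected
tail; the 0.13% dynamic-FP identity itself is an analytic statement
about the model, asserted exactly. The workbench's pixel-count check
also excludes lesion-bearing slices: PSF rims just outside the truth
mask are genuine threshold crossings, not blood-pool noise, and would
otherwise inflate the measured FP by ~20%.

## Cohort statistics

Welch t-tests (Satterthwaite df, two-tailed) and OLS simple regressions
delegate to scipy/statsmodels; slopes are reported per stated unit
(decade, 10 kg, level, mm) by exact scaling. Adjusted R² is reported —
it can be negative for uninformative predictors, which plain R² cannot.
Significance tiers are p < 0.01 and p < 0.001; no multiple-testing
correction is applied. The paired plaque-pixel regression generator
draws x from the plaque law and sets y = 1.1x + 2.7 + ε with
SD(ε) = 1.1·SD(x)·√(0.03/0.97), targeting adjusted R² = 0.97; at
n = 5000 the slope is recovered to ±0.01.

## Problem sizes and determinism

Default validation sizes: 10⁶ plaque-law samples for distribution
calibration; 10,000 scans for population Monte-Carlo; ~70 large
plaque-free phantom slices (>10⁶ blood pixels) for the pixel-level FP
check; 2,000 tiny-geometry scans for covariate recovery; pipeline runs
of 60–120 scans at 48–64 px slices. These sizes put every Monte-Carlo
tolerance (3·SE) well inside the reported rounding conventions
(percentages to 5 points, thresholds to 50 HU) while keeping any single
check under a minute. All randomness flows from explicit seeds through
`numpy.random.Generator` spawn keys; identical (params, seed) produce
bit-identical cohorts, tables and reports.

## Known limitations

* The plaque law is a two-parameter stand-in for an unpublished
  histogram; absolute FN magnitudes under the dynamic scheme inherit
  its shape.
* Venous and non-contrast population parameters are placeholders.
* Blood-pool pixels are spatially independent; real CT noise is
  correlated, so empirical SDs on real scans may behave differently
  under erosion than phantom SDs do.
* The 2-D per-slice lesion model cannot represent through-plane partial
  volume; slice thickness enters only as a volume multiplier.
* Explicit-list populations assume every scan's blood pool is exactly
  normal; heavy-tailed contamination (streak artifacts, stents) is not
  modelled.
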