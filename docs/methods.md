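# Methods

`suvvar` estimates the *statistical technical variation* of PET SUV
metrics: the part of SUV test–retest variability that is caused by
radioactive-decay counting statistics alone, as opposed to biological
variability or protocol/technical factors.  The estimate is obtained from
a single acquisition, without rescanning.

## The estimator

A list-mode acquisition of length T (default 150 s per bed position) is
partitioned into subsets of statistically independent frames of shorter
reconstruction length RL: the half-open intervals [0, RL), [RL, 2·RL), …
give ⌊T/RL⌋ disjoint frames that share no coincidences.  With the default
fourteen subsets (RL = 4, 6, 8, 10, 12, 15, 17, 19, 20, 22, 24, 26, 28,
30 s) a 150 s acquisition yields 37 frames at RL = 4 s down to 5 frames
at RL = 30 s.  Remainder seconds (150 mod RL) are dropped rather than
pooled into a short final frame, so every frame in a subset has the same
length and hence the same variance.

For each subset, each sphere and each SUV metric, the coefficient of
variation across the frames is

    CoV% = 100 · SD / mean,

with the sample SD (n−1 denominator).  Because count noise scales as the
inverse square root of the acquisition time, the CoV expected at another
reconstruction length RL₂ is

    SD₂ = SD₁ · √(RL₁ / RL₂).

Each subset therefore provides one estimate of the CoV at the full length
(RL₂ = 150 s); the mean of the 14 estimates is the headline result and
their SD quantifies the estimation uncertainty.  The extrapolation is
applied to the scale-free CoV% rather than the raw SD, so the frame mean
only enters once.  A leave-one-out variant extrapolates every subset's
CoV to every *other* subset's RL (13 estimates per target), which is the
standard internal-consistency diagnostic: if the square-root law holds,
the estimates scatter around the directly measured CoV with no trend in
the source RL.

Assumptions: frames are independent and identically distributed within a
subset (guaranteed by the disjoint-interval construction and decay
correction), the metric populations are approximately normal (checked
with a Kolmogorov–Smirnov test against a normal with fitted moments, on
raw and log-transformed values), and the metric's noise SD follows the
RL^(−1/2) law.  The last assumption is exact for linear metrics (Mean)
and approximate for order statistics (Max, Peak); see *Limitations*.

Pairwise differences between the 14-estimate populations — adjacent
sphere sizes within a metric (5×5 tests) and metric pairs within a sphere
(10×6 tests) — are assessed with two-sided Welch t-tests
(Welch–Satterthwaite degrees of freedom) at α = 0.05, unadjusted; a
Holm-adjusted column is emitted alongside for transparency.

## SUV metrics and regions of interest

All values are activity concentrations in kBq/ml — a phantom has no body
weight, so no SUV normalisation is applied (a scale factor can convert to
clinical SUV).  Per sphere and frame:

* **Max2D / Max3D** — maximum voxel value in the central axial disk / in
  the 3-D sphere mask;
* **Mean2D / Mean3D** — arithmetic mean over the same masks, with no
  thresholding;
* **Peak** — mean over a 1 cm³ ball (radius (3000/4π)^⅓ ≈ 6.204 mm)
  centred on the hottest voxel of the sphere mask.  The ball is *not*
  clipped to the sphere; background spill-in is inherent to the metric.

Masks use the center-in rule: a voxel belongs to a region iff its center
lies inside.  On the default 4 mm grid this gives 7 voxels for the 10 mm
sphere (19 for 13 mm), 5 voxels for its central disk, and 19 voxels for
the 1 cm³ ball.  The SUVMax search is restricted to the nominal sphere
mask (3-D) or central disk (2-D); argmax ties break to the lowest
lexicographic index, and a sphere center equidistant from two slices
takes the lower slice — both purely for determinism.  ROIs are detected
once on a reference image and reused for every frame of every subset, so
the measured variation isolates counting statistics rather than
segmentation variability.

Sphere detection runs in two modes.  With a phantom layout available
(the default for simulated data) the known centers are refined by an
intensity center-of-mass within each nominal sphere.  Automatic mode
smooths lightly, reduces plateaus of tied local maxima to single
candidates, picks the six strongest candidates at least 20 mm apart,
sizes each by the volume of its half-contrast isocontour (50% between
the background level and the local max — background-corrected because a
plain 50%-of-max contour swells small low-recovery spheres), and matches
candidates to the expected diameters by size rank.

## The phantom simulator

The simulator replaces the scanner and list-mode reconstruction with a
direct model of *reconstructed, decay-corrected* frames, because that is
what the estimator consumes; no sinogram, OSEM, attenuation or scatter
modelling is attempted.

**Geometry.** Image-quality phantom: six spheres of 10, 13, 17, 22, 28
and 37 mm diameter on a 57.2 mm-radius ring at 60° spacing in one axial
plane, a cold 25 mm-radius central cylinder, and an elliptical torso
background (semi-axes 150 × 115 mm).  Default concentrations at scan
start: 2.10 MBq/ml background, 20.04 MBq/ml spheres (the stored
concentrations give a computed ratio of ≈ 9.54:1; the nominal aim is
10:1).  Grid: 144 × 144 in-plane, 48 axial slices, 4 mm isotropic
voxels, voxel-center convention.  Ground truth is rasterised with
partial-volume fractions from 5³ sub-voxel sampling per boundary voxel.

**Counting noise.** Expected counts per voxel are
μ = c · V_voxel · s · RL · f_decay, with c the truth concentration,
s the system sensitivity and f_decay the frame-averaged F-18 decay
factor (half-life 109.7 min), computed as the exact integral of
2^(−t/T½) over the frame rather than its midpoint value.  Counts are
drawn Poisson(μ) and divided by the same factor, so frames are
decay-corrected to acquisition start and their expectation is
frame-start independent.  Every frame uses an independent random
substream keyed by (seed, subset index, frame index), mirroring the
statistical independence of disjoint list-mode intervals.

**Noise texture.** By default the raw Poisson field is smoothed with a
6 mm FWHM Gaussian *after* sampling.  Iteratively reconstructed PET
images have spatially correlated noise on roughly the resolution scale
(~5–7 mm for the class of whole-body systems emulated), and this
correlation is load-bearing for the estimator: with strictly independent
voxel noise at realistic noise levels, the short-RL inflation of the
expected Max/Peak deflates their measured CoV enough to bias the
square-root-law extrapolation low, and a max-centred Peak on a perfectly
flat noise field acquires a large positional variance that no real
reconstruction shows.  Smoothing is linear, so each output voxel remains
a fixed linear combination of independent Poisson variables and the
RL^(−1/2) noise-SD law is exact.  Setting `post_noise_fwhm_mm = 0`
recovers independent voxel noise with per-voxel CoV exactly 1/√μ (used
in the unit tests of the Poisson machinery); `psf_fwhm_mm` optionally
blurs the truth before noise instead.

**Noise level.** The sensitivity default (3.0 × 10⁻⁴ counts per kBq·s)
was calibrated once so that the SUVMax CoV of the 10 mm sphere at
RL = 4 s is ≈ 27%, inside the 20–30% regime the method is designed to
probe (the regime where technical variation stops being negligible), and
then frozen.

**What the simulator does not emulate.** Reconstruction non-linearity
and bias, edge ringing, object-dependent noise correlation, scatter and
attenuation-correction residuals, sphere walls, and randoms.  Passing
tests therefore show that the *estimator* behaves as designed on frames
with calibrated counting statistics — not that any particular scanner
attains these numbers; the absolute CoV values are simulator-specific,
exactly as real ones are scanner-specific.

## Numerical choices and degenerate inputs

* CoV requires ≥ 2 values and a non-zero mean; schedules with a single
  frame are rejected for estimation.
* The KS normality test needs ≥ 5 values when fitting the reference
  moments; a fully specified reference normal is accepted for any n.
  A Lilliefors-corrected variant is available behind a flag but off by
  default.
* The Welch test handles the zero-variance degenerate pair as t = 0,
  p = 1 with pooled df.
* The square-root-law round trip RL₁ → RL₂ → RL₁ is exact to 1e-12
  relative; interval endpoints are exact in integer seconds.
* A 1 cm³ ball clipped by the grid boundary is used as-is with a
  recorded warning.
* Frame I/O: one NIfTI file per frame plus a JSON sidecar
  (frame start, duration, decay reference, voxel size); frames are
  grouped by duration on load and grid consistency is enforced.

## Problem sizes

The default study simulates 166 frames (all fourteen subsets of a 150 s
acquisition) on the 144 × 144 × 48 grid; estimator-validity checks
additionally simulate 100 independent 150 s frames and compare the
extrapolated estimates against the directly measured CoV.  Statistical
calibrations use 1000 null replicates (Welch) and 50 Gaussian samples of
n = 200 (KS).  These sizes give Monte-Carlo errors comfortably below the
effects being tested while keeping a full run in well under a minute.

## Known limitations

* **SUVPeak on flat-topped spheres.**  When the blurred sphere interior
  is an exactly flat plateau and (plateau radius + 6.2 mm ball radius)
  reaches the sphere boundary — the 28 mm sphere on the default setup is
  the worst case — the argmax position is a noise-scale-independent draw
  over the plateau, and the ball's background spill-in varies with that
  position.  SUVPeak then carries a positional variance floor that does
  not scale as RL^(−1/2), and the extrapolated estimate underestimates
  the directly measured full-length CoV for that sphere (by roughly
  2–4 SD-of-estimates across seeds; all other metric × sphere cells
  agree within 2 SD).  Real phantoms break the tie with small systematic
  non-uniformities; the simulator deliberately does not invent them.
* The Max metrics' short-RL mean inflation makes the CoV extrapolation
  mildly conservative (estimates sit slightly below the measured CoV);
  the effect is within the estimator's own spread under the default
  conditions.
* No multiple-testing correction is applied to the pairwise tables by
  default (the Holm column is informational).
* Single bed position only; multi-bed acquisitions are out of scope.
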