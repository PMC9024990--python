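# Methods

## Conventions

Volumes are 3-D grids indexed `(slice, row, col)`; a "transverse slice" is
a fixed first index.  Spacing is `(dz, dy, dx)` in mm with `dz` the
inter-slice distance; the default phantom grid mirrors a whole-body FDG PET
reconstruction, 168×168 in-plane at 4.06 × 4.06 × 2.5 mm.  Pixel membership
in an ellipse is decided by pixel-center inclusion.  SUV is body-weight
SUV, C·(weight in g)/(dose in kBq), with tissue density 1 g/mL; decay
correction of the dose is the caller's responsibility.

## Adaptive-threshold PET segmentation

The expert draws an ellipse around the lesion on the central slice.  The
background ring (default width 3 pixels) is placed **just inside** the
ellipse boundary: the expert draws around the tumor, so the inner margin
samples background and edge tissue while keeping the whole computation
within the expert-delimited region.  An outside ring is available
(`ring_inside=False`).  Ring membership uses the Euclidean distance to the
ellipse boundary, evaluated against a dense (2048-point) boundary sample —
exact to well below a hundredth of a pixel at these ring widths.

Thresholding is literal: pixels strictly greater than `f ×` reference are
candidates, with the reference being the ring mean (default) or the
maximum intensity inside the ellipse (`roi_max`, the conventional
fraction-of-max alternative).  Of the candidate connected components
(8-connectivity by default), the one containing the in-ellipse pixel
nearest the ellipse center is kept; if that pixel is not a candidate, the
largest component is used, ties broken by the lexicographically smallest
(row, col) member.  An empty mask is a valid outcome (lesion resolved).

Projection applies the identical elliptical footprint to successive slices
in both directions, recomputing the ring mean per slice (a flag reuses the
central value instead), and stops in a direction at the first slice whose
mask falls below `min_component_pixels` (default 1) or after
`max_slices_each_side` (default 20) slices.

**Degenerate rings.**  The ring-mean rule assumes the ring straddles the
lesion boundary, so its mean sits between background and lesion uptake.
Two degeneracies follow from the rule itself and are handled explicitly:

* On a slice whose ring is entirely zero (cold surround beyond the lesion
  extent), the threshold would be 0 and meaningless.  During projection
  such a slice falls back to the in-ellipse maximum as reference; an
  all-zero slice yields an empty mask and stops the projection.
  `segment_slice` called directly still requires a positive ring mean.
* With a strictly positive *uniform* warm background, every in-ellipse
  pixel exceeds `f·background` for any `f < 1`, so the mask never empties
  and projection is bounded only by `max_slices_each_side`.  This is an
  inherent property of the literal rule, not an implementation artifact;
  on real scans the surround is heterogeneous and the expert's central
  slice choice bounds the lesion.  Phantom defaults therefore use a cold
  (zero-activity) surround, which keeps the stop rule exercised.

Threshold nesting (a higher fraction can only shrink the mask) is
guaranteed when the seed pixel remains a candidate at the higher fraction
— always true for the phantoms' lesion-centered ROIs.  When the seed drops
below threshold the largest-component fallback can, in principle, select a
different clump; this is documented rather than patched, since any other
fallback is equally arbitrary.

## Size metrics

MTDmax is the maximum pairwise distance between true-pixel centers on the
selected slice (the mask's central slice by default, matching single-image
clinical practice), computed brute-force up to 2000 pixels and via convex
hull above; a single pixel has diameter 0 because distances are between
centers, with no margin added.  MTAmax is the true-pixel count × dy·dx;
MTV is the voxel count × voxel volume.  The expert's manual volume
surrogate stacks per-slice ellipses and counts contained pixel centers.
CT metrics reuse these operations unchanged.

## CT segmentation

A simplified faithful sketch of a wavelet + fuzzy C-means + MRF pipeline;
the upstream publications describing the original's internals are not
reproduced, so every default here is this package's own choice and exposed
as a parameter.  Per-slice orthogonal wavelet shrinkage (db2, universal
threshold, MAD noise estimate on the finest diagonal band) precedes FCM
(c = 3 for air/soft-tissue/lesion, fuzzifier m = 2, seeded jittered
quantile initialisation; the objective is non-increasing and asserted so
in tests).  Hard labels are refined by iterated conditional modes under a
Gaussian-likelihood + Potts energy, E = Σ (xᵢ−μ_l)²/(2σ_l²) + β·#{unequal
neighbor pairs}, β = 1, 6-connected neighborhoods, class statistics
re-estimated each sweep, variances floored at 10⁻⁶; an emptied class is
re-seeded at the voxel nearest its last mean, with a warning.  The tumor
is the refined class whose mean matches the highest FCM cluster mean
inside the ROI — a documented heuristic (lesions are the bright class in
the windows used here).  `min_component_pixels` doubles as the no-lesion
detector: in a structureless ROI the bright class survives only as small
noise clumps, far below any plausible lesion cross-section.

## Response classification

Δ = (post − pre)/pre × 100, undefined for non-positive baselines (such
rows are reported, never dropped).  Boundaries follow the printed symbolic
intervals: CMR exactly −100, PMR (−100, −30], SMD (−30, 20), PMD [20, ∞)
or new lesions (an explicit caller flag; lesion detection is out of
scope).  A configurable `cmr_tolerance` (default 0) lets a caller accept a
few residual segmented voxels as complete response, since a visually
resolved lesion can leave the segmenter a handful of pixels.

## Agreement statistics

Bland–Altman uses expert − CAD differences, the n−1 SD, and limits
bias ± 1.96·SD.  Weighted kappa uses linear weights w₍ᵢⱼ₎ = 1 − |i−j|/(k−1);
the standard error is the Fleiss–Cohen–Everitt large-sample formula and
the 95% CI is κ ± 1.96·SE clipped to [−1, 1], with a multinomial bootstrap
as an alternative.  The CI choice is validated by simulation: cohorts of
45 subject pairs drawn from an explicit joint class table (two
conditionally independent raters of 70% accuracy over a
mostly-responding class mix) whose population κ has a closed form; the
asymptotic CI covers it in ≈93–95% of 1000 replicates.  Landis–Koch
adjectives are annotation only.  The t-test defaults to pooled variance
(Welch available) and the 2×2 chi-square is uncorrected by default (Yates
available).

## Threshold sweep

Fractions {0.3, 0.4, 0.5, 0.6, 0.7} are each scored against a reference
outline by Dice (primary criterion; a single standard scalar), with
sensitivity, specificity and signed volume error reported alongside.
Specificity is computed within the projected ellipse footprint — over the
whole volume it saturates trivially.  Ties select the lower fraction.  The
matched-optimum check constructs its reference outline as the
50%-of-ring-mean isocontour (i.e., the segmentation at f = 0.5 of a
PSF-blurred phantom, taken as the expert ground truth), so 0.5 is the
correct answer by construction and the sweep must rank it first.

## Phantoms

Lesions are axis-aligned (optionally in-plane-rotated) ellipsoids:
irregular lymphoma shapes cannot carry analytic ground truth, so realism
is traded for exactness.  Truth (mask, 4/3·π·abc volume, central-slice
area and diameter, SUVmax) is fixed before PSF blur and noise — blur is a
measurement degradation, not a change of truth.  Defaults: lesion SUV 8
over a cold surround, axial semi-axes chosen so extents span the 5–20
slice clinical range; degradation off (noise and PSF are opt-in per
study).  The `suggest_roi` margin of 1.5 pixels makes the 3-pixel ring
straddle the lesion boundary, anchoring the ring-mean threshold between
background and lesion uptake.  Pre/post pairs scale semi-axes by the cube
root of a volume factor so the true ΔMTV is exact; class-targeted draws
stay 1 percentage point clear of shared interval boundaries.  Measurement
cohorts draw lognormal baselines of clinically plausible magnitude (MTV
~1.2·10⁵ mm³, MTDmax ~70 mm, MTAmax ~2.5·10³ mm², SUVmax ~10) and apply
independent lognormal reading noise per rater; a vanished lesion is read
as zero by both raters, so complete response survives reading noise.

What the phantoms do **not** emulate: scatter/randoms/reconstruction
artifacts, heterogeneous anatomical background, irregular or multiple
lesions, PET–CT misregistration.  Passing tests therefore demonstrate the
correctness of the measurement chain on separable geometry, not clinical
segmentation accuracy.

## Problem sizes

Test and acceptance runs use the default 168×168×40 grid (or a 96×96×24
variant for the randomized sweeps), 40–100 random phantoms for the nesting
properties, 20 pre/post pairs for class recovery, 200–1000 random tables
for the kappa oracle, and 1000 replicates for CI coverage — sizes at which
every Monte-Carlo margin in the tests is comfortably stable.

## Known limitations

* The ring-mean rule's warm-background degeneracy (above) means MTV on a
  uniform warm surround depends on `max_slices_each_side`; use `roi_max`
  or a heterogeneous background model in that regime.
* The CT pipeline is a sketch: cluster count, β and wavelet family are
  package defaults, not values from any clinical validation.
* Diameters between pixel centers understate outer-boundary diameters by
  up to one pixel diagonal; clinical readings that add a margin will read
  systematically larger.
* No multi-lesion support: one lesion, one expert ellipse per study.
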