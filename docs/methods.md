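# Methods

`anchorreg` registers microscopy images against a *predefined structural
model* rather than against another image. The model contributes a list of
anchor points `P_m` — coordinates of features the instrument can actually
resolve (lattice sites, corner holes, device corners) — expressed in
unit-length normalised model coordinates. Registration estimates the planar
projective map that carries the model onto the points extracted from the
image, which simultaneously (i) aligns frames taken under different
conditions on an absolute scale, (ii) corrects the slow non-linear scan
errors (thermal drift, piezo creep) typical of scanning-probe imaging, and
(iii) localises sub-features such as adatoms from the model's internal
geometry.

## Coordinate conventions

Points are `(x, y)` with `x` the column and `y` the row index, origin at the
top-left pixel centre, 0-based. Transform matrices are 3x3 with the
bottom-right entry normalised to 1 after every product and inversion, so
entrywise comparisons are meaningful.

The affine placement matrix is composed as `A = S(s_x, s_y) R(theta)
Sh(a_x, a_y) T(x_0, y_0)` in exactly that factor order. Because the
translation is the right-most factor it acts in pre-rotation (model)
coordinates; the brute-force translation search therefore operates in model
units. A homography `H` replaces the two zero entries of the bottom row
with projective terms `(g, h)`.

## The two-stage registration chain

**Rough matching.** Candidate points `P_e` come from one of the extractors
(below) or directly from the caller. For periodic models the vote filter
scores every point against its neighbours within a candidate radius
(default `1.3 L`, which spans the four axial neighbours of a square lattice
but not its diagonals): +1 for a neighbour whose distance falls inside
`[0.9 L, 1.1 L]`, -1 otherwise; points with negative score are dropped,
isolated points (score 0) are kept. The affine parameters other than
translation come from prior knowledge — pixel scale from the model's
inter-structure distance, rotation from the experimental setup — and the
translation is found by brute force: the grid is centred on the
centroid-aligning translation and spans one primitive cell (translation is
only identifiable modulo the lattice) at step `L/50`, or the model's own
extent for polygon models. The placement objective is the *median*
nearest-neighbour distance from the placed model to `P_e`, robust to
missing detections and to spurious points. Pairing is greedy
nearest-neighbour with a distance gate (default `0.35 L` in placed units,
ascending-distance order, ties to the lowest model index); each extracted
point is claimed at most once. On instances where every model point has a
unique partner well inside the spacing this greedy rule coincides with the
optimal assignment; it is not a global optimiser on adversarial inputs.

**Fine matching.** The homography is estimated from the surviving pairs by
least median of squares (LMedS). Minimal 4-pair subsets are solved by the
direct linear transform with Hartley normalisation (centroid to the origin,
RMS radius sqrt(2)) — unconditionally required for numerical stability —
and each candidate is scored by the median squared reprojection error over
*all* pairs; the minimiser wins. With exactly four pairs the interpolating
solution is returned directly. `n_samples` defaults to 1000 subsets; all
subset sampling is driven by the config seed, so runs are reproducible.

**Refinement.** A least-squares re-solve over inliers follows by default
(`refine=True`). Bootstrapping the inlier set needs care, and two failure
modes shaped the design:

* the winning minimal subset is interpolated exactly, so a noise scale
  taken straight from the median of its residuals collapses towards zero
  for ~9-point problems and a single refit then "confirms" a 5-point
  overfit (measured: recall at 9 points / noise 0.07 drops to ~0.78 while a
  plain least-squares fit scores 1.0);
* any scale estimated from a *subset* of the residuals can be corrupted
  when the complementary subset is majority-outlier.

The implementation therefore splits the sorted squared residuals of the
best minimal hypothesis at the largest multiplicative gap in their upper
half: gross mispairings sit orders of magnitude above inlier residuals, so
a gap ratio above 100 marks the outlier boundary, and with no convincing
gap every pair enters the refit (plain least squares, correct under pure
detection noise). The lower group always keeps at least six points so a
refit can never approach interpolation (12 equations against 8 degrees of
freedom). The refit then iterates the standard rule — inliers are pairs
within `2.5` robust scales, `sigma = 1.4826 (1 + 5/(n-4))
sqrt(median_sq_residual)` — to convergence (at most 10 passes), which is
well posed once the fit no longer interpolates.

**Reconstruction.** Extracted points are carried back to model units as
`P_t = A^{-1} H^{-1} P_e`; rectification applies the same composite to the
whole image (bilinear resampling, configurable fill), scaled so anchors
land on exact pixel positions spaced `pixels_per_unit` apart. The paper
trail for a registration (placement, pairs, estimate, metrics, status) is
kept in `RegistrationResult`. If fewer than four pairs survive, placement
is retried once with the gate widened 1.5x (status `degraded`); if
estimation is still impossible the result is `failed` with a reason.

## Point extraction

* **Dark keypoints** (corner holes): Gaussian smoothing (default sigma
  1 px), local minima (or multi-scale difference-of-Gaussian extrema for
  the `sift_like` detector), a depth gate at 25 % of the mean-to-minimum
  range to reject noise extrema, and the below-mean intensity filter.
  Sub-pixel positions come from a parabolic fit refined by an iterative
  Gaussian-weighted depth centroid (window tied to `min_separation`), which
  removes the parabola's small systematic bias: ~0.4 milli-pixel accuracy
  on clean symmetric wells, ~0.1 px at SNR 20. Minimum separation is
  enforced by keeping the darker of any conflicting pair. The detector is a
  scale-robust blob localiser, not a descriptor pipeline: descriptors are
  never used downstream.
* **Square corners** (device outlines): Gaussian blur, Otsu initialisation
  refined by intermeans iteration (this places the binarisation boundary at
  the blurred edge's half maximum, i.e. on the true outline), largest
  connected component, then the minimum-area rotated rectangle of the
  component's half-pixel-buffered convex hull. Corners are ordered
  counterclockwise starting nearest the image origin; the component
  centroid is returned alongside.
* **Site classification** (adatom vs defect): the mean of a `(2w+1)^2`
  patch (default 5x5) is sampled at every projected site. The default
  threshold adapts to the sample population: when the sample spread exceeds
  a noise floor (8 robust image sigmas scaled by patch averaging) the
  population is bimodal and the midpoint of its extremes separates the two
  classes regardless of how unbalanced they are; otherwise all sites share
  one label, chosen by comparing the median sample against the image
  median (a constant image is deterministically all-present). A fixed
  threshold can always be supplied. A percentile-midpoint rule was
  considered and rejected: with rare defects both percentiles fall inside
  the majority cluster and the midpoint splits it by noise.

## Unit-cell encoding and cross-frame matching

The Si(111)-(7x7) half cell is modelled as an equilateral triangle of
corner holes with side 1 (corner-hole distances normalised to 1) and six
adatom sites: corner adatoms 1-3 counterclockwise from the lowest-left
corner hole at barycentric coordinates (5,1,1)/7, then centre adatoms 4-6
in the same angular order at (1,3,3)/7. Only the relative geometry matters
for registration; the full dimer-adatom-stacking-fault model (rest atoms,
dimers) is out of scope. Whether the published six-element vector covers a
half cell or alternates faulted/unfaulted halves is ambiguous; encoding
here is per triangular half cell, and the numbering above is the package's
fixed convention.

Each complete cell whose anchors were matched gets a binary vector (1 =
adatom present, 0 = defect) in template order, classified in a single
global pass so the adaptive threshold sees all cells at once. Frames are
matched by exact vector identity, disambiguated by the single lattice
translation consistent with the most matches; a tie, or frames whose cells
all share one vector, is reported as ambiguous with a diagnostic rather
than guessed (boundary effects would otherwise bias the vote towards zero
offset).

## Registered-image comparison

`difference_map` subtracts aligned images pixelwise without intensity
normalisation (an optional histogram-matching flag exists for
cross-condition optical images) and reports the fractional change of the
dark-signal integral `S = sum(max(0, baseline - I))`, baseline defaulting
to the Otsu threshold of the first image; the definition of the integral,
its baseline and region are configurable since only a percentage change is
meaningful. `line_profile` samples bilinearly at unit-pixel spacing,
averaged across integer perpendicular offsets.

## Monte-Carlo validation

The accuracy study asks how anchor-detection error propagates through
estimation. Per sample: build an `n x n` unit lattice, draw a random
homography (uniform perturbations of the identity — scale ±0.1, rotation
±0.1 rad, shear ±0.05, translation ±0.5, projective terms ±0.01 per unit;
draws are rejected unless invertible with positive depth over the lattice
extent), transform the lattice, add i.i.d. Gaussian coordinate noise in the
image frame, re-estimate the homography from the noisy correspondences, and
reconstruct `P_t = H_est^{-1} P_e_clean`. Reconstruction targets the
*noise-free* transformed positions deliberately: rectification warps the
whole image, and reconstructing the noisy points through a 4-point
interpolating fit would be exactly error-free, which cannot measure
anything.

Accuracy is summarised by MAE — the mean Euclidean distance between `P_t`
and `P_m` in model units (a per-axis variant would be possible; mean
Euclidean is used throughout) — and by Recall@OKS: the fraction of samples
whose Object Keypoint Similarity exceeds 0.95, where OKS is the mean
per-point Gaussian similarity `exp(-d^2 / (2 s^2 kappa^2))` with `s` the
unit length. The falloff constant is a free parameter of the metric;
`kappa = 0.5` was calibrated once, within the range considered plausible
(0.1-0.5), so that the 4-anchor-point / noise-0.05 condition reproduces the
published >= 0.9 recall together with the grid-wide bound below, and is
fixed thereafter. Per-point kappa variation (as in COCO keypoint
evaluation) is unnecessary here because all sites are equivalent.

Study conditions mirror the published sweep: noise std 0 to 0.1 crossed
with square point counts 4-49, 10,000 samples per condition in the full
study. The test suite and acceptance script run the same generator at
500-2000 samples per condition — chosen as the package's desk-scale
defaults — with the LMedS subset count at 200 (no outliers are injected by
the sweep, so subset count only affects hypothesis diversity). The sweep is
bitwise reproducible from its seed (conditions are seeded by spawned
`SeedSequence` children, so per-condition results do not depend on grid
order). Estimation failures are recorded as MAE = +inf, OKS = 0 and
flagged, never silently dropped.

## Synthetic fixtures: what they do and do not emulate

`render_fixture` draws dark Gaussian wells at anchor positions mapped
through a known homography (the well shape itself is kept isotropic — at
the mild distortions studied the centre shift, which is what registration
consumes, dominates any shape anisotropy), bright Gaussian spots at present
sub-features, i.i.d. Gaussian pixel noise at a chosen SNR
(`noise std = well depth / SNR`), and emits ground truth alongside. Same
seed, same image. Real SPM/OM images additionally contain scan-line noise,
intensity gradients, tip-shape convolution and contrast inversions; passing
on these fixtures therefore demonstrates the geometric correctness and
noise behaviour of the chain, not robustness to every instrumental
artefact. The extractors expose their thresholds precisely because real
data need tuning.

## Numerical choices and degenerate inputs

* Matrices with `|det| <= 1e-12`, or homogeneous depth `|z| < 1e-12` at any
  point, raise typed errors (the projection error names the offending
  indices). Whole-image warping substitutes the fill value for pixels whose
  pre-image is at infinity instead of failing.
* Bilinear interpolation for all resampling; the source never states an
  interpolation scheme, and bilinear at integer grid positions reproduces
  the input exactly, which the tests exploit.
* DLT systems with a singular-value ratio below 1e-10 (three collinear
  points in a subset) are rejected; sampling simply skips them, and an
  all-degenerate run raises.
* Rectify-then-re-register returns the identity exactly in point space;
  through pixels it is limited by resampling and sub-pixel detection bias
  (~5e-3 px systematic on noise-free renders), so image-level idempotence
  is asserted at 0.02 entrywise while rectified anchors land on the ideal
  grid to ~0.013 px.

## Known limitations

Rotation and scale must come from prior knowledge — there is no rotation
search, by design (the instrument's scan geometry provides them). The vote
filter presumes distortion mild enough that neighbour spacings stay within
±10 % of `L`; severe perspective (homogeneous depth varying tens of percent
across the field) strips valid points, which is the documented filtering
behaviour, not an accident. Greedy pairing and the translation-vote frame
matcher can differ from globally optimal assignments on adversarial
configurations. LMedS breakdown degrades below ~12 pairs when half the
pairs are wrong.
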