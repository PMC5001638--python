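# Methods

`madetect` detects retinal microaneurysms (MAs) — the earliest visible
lesions of diabetic retinopathy, small dark round spots of radius roughly
1–6 px at a 768-px image width — in color fundus photographs.  Detection is
two-staged: a deliberately permissive *candidate extraction* stage that
rejects only the obvious non-lesions (vessels, flat background), followed by
a *candidate classification* stage that scores each candidate with a
class-imbalance-aware ensemble.  All resolution-dependent parameters scale
with `rho = image_width / 768`.

## Candidate extraction

**Preprocessing.**  The green channel (highest lesion contrast) is smoothed
with a median filter of radius `round(rho)` and shade-corrected by
subtracting a median-filter background (window radius `25 rho`), re-offset
to mid-range 0.5.  A median was chosen as the edge-preserving smoother: it
is an order statistic, so it cannot overshoot or ring by construction, it
does not displace monotone step edges, and it removes less than 20% of the
depth of a sigma = 2 px Gaussian lesion — a contract that bilateral and
guided filters at practical range scales failed by wide margins (40–55%
depth loss measured).  Pixels outside the field of view (FOV) are excluded
from the background estimate and set to 0.5 so the FOV rim does not create
a dark ring of false candidates.

**Vesselness (K map).**  For each pixel and each integer support radius
`r = round(2 rho) … round(7 rho)`, the 2×2 covariance **C** of the image
gradient vectors over the disk of radius *r* is formed (population
normalization, mean-subtracted).  On a vessel — a linear ridge — gradients
point along the ridge normal with both signs, giving one dominant
eigenvalue; at the center of a round blob the gradient distribution is
isotropic.  The score

    K = sum_r ln( (lambda1 + eps) / (lambda2 + eps) )

is therefore large on vessels and near zero on lesions.  `eps` guards the
zero-covariance case.  Its value matters: the eigenvalues of faint, wide
vessels (contrast ≈ 0.09 after shade correction, half-width ≈ 5 px) are of
order 1e-7–1e-6, so `eps = 1e-6` flattens exactly the vessels that most
need removing.  The default is `eps = 1e-8`: two orders below those
eigenvalues, yet two orders above the float cancellation noise of
`lambda2` (≈ `lambda1 · 1e-16`), which keeps the map reproducible to 1e-9
against a brute-force reference.  The disk sums are computed by exact
row-cumulative sums (no FFT), so the vectorized map agrees with per-pixel
enumeration to float precision.

**Vessel removal.**  Thresholding K at 14.5 (rescaled by `n_scales / 6` when
`rho ≠ 1`, since K is a sum over scales) yields a binary marker of strongly
vessel-like pixels.  In the complement image `J = 1 − I_p`, grayscale
reconstruction by dilation (8-connectivity) of mask `J` from marker
`J · (K ≥ 14.5)` rebuilds the vessel network; round lesions, disconnected
from vessels and unmarked, cannot be reconstructed.  The residual `J − R`
is ≈ 0 on vessels and keeps each lesion's complement contrast.  The whole
operation stays in the complement domain, so lesions appear as bright peaks
in the residual.  Vessel *crossings* are a known failure mode: a crossing
is locally blob-like (low K, unmarked) and brighter in `J` than either arm,
so a residual peak of roughly the weaker vessel's contrast survives there —
these become candidates and are left for the classifier.

**Localization (P map).**  At a blob center the 1-D profile has a minimum
in every direction; on a ridge at least one direction is flat.  For 36
directions (10° steps), the first directional derivative of the (negated)
residual is computed from a 7×7 cubic facet model — a per-pixel bivariate
cubic least-squares fit implemented as fixed convolution kernels, which
reproduces planes and quadratics exactly — floored at zero, and
differentiated again along the same direction.  P is the product of the 36
positive parts, accumulated in the log domain with a zero short-circuit.
Factors below 1e-12 count as zero: that is the scale of float dust the
convolution pipeline leaves on analytically flat profiles, many orders
below any genuine blob response.  Two numerical caveats are documented by
the tests: direction cosines are snapped to 0 at multiples of 90° so
axis-aligned directions are exact, and the facet estimator is a smoothing
derivative filter whose curvature bias is O((3/sigma)^2) — its absolute
second-derivative accuracy is only meaningful for structures with
sigma well above the window half-width.

Candidates are the 8-neighborhood local maxima of P (plateaus collapsed to
centroids, minima closer than 2 px deduplicated to the higher P) above a
relative threshold of 0.1.  The threshold is applied on the 36th root of P
(the per-direction geometric mean): the raw product spans a dynamic range
exponential in the direction count — two lesions whose contrasts differ
4-fold differ by 4^36 in P — so a relative cut in product domain would keep
only the single strongest blob, which contradicts the method's goal of
preserving subtle lesions.  On the root scale, blob strengths of different
contrast are commensurate and 0.1 behaves as a permissive noise floor.

**Segmentation.**  Each candidate grows from a 2-px disk under a localized
Chan–Vese model: a boundary pixel joins (leaves) the region according to
the sign of `(I − v)² − (I − u)²`, where `u` and `v` are the interior and
exterior means restricted to a ball of radius `8 rho` around that pixel.
Only pixels adjacent to the current boundary may flip per iteration (a
1 px/iteration CFL-type bound; this narrow-band bookkeeping also makes the
per-iteration cost proportional to contour length), and a hysteresis 3×3
vote (members persist at ≥ 4/9, outsiders join at ≥ 6/9) acts as curvature
regularization.  A plain majority vote was rejected because it
systematically erodes the four cap pixels of every rasterized disk.
Segmentation runs on `I_p`, not the residual, so region statistics reflect
true image contrast.  Known limitation: for lesions 2–4 px from a vessel,
the dark vessel inside the local ball can either absorb the contour or
drag the exterior mean low enough to collapse it; the exclusion criterion
then removes the region, costing a small fraction of vessel-adjacent
lesions.

## Features (1247 per candidate)

Seven families; the layout is fixed and versioned
(`madetect-features-1`): geometric (6), contrast (10), intensity (42),
edge (1), texture (16), HOG (775 = 5×5 cells × 31), SURF-style
(128 = 4×4 × 8), GIST (216 = 3 scales × 8 orientations × 3×3 grid), other
(53).  The published family counts do not determine a unique accounting;
this package's canonical split of the 53 "other" slots is: 36 per-direction
mean angle differences between the gradient and the sampling ray + their
overall mean/std (2) + inside/outside mean/std in the single-scale
(r = 4 rho) condition-number map, the convergence-index map (disk radius 5)
and the divergence map (12) + isolated-index mean/std over the region (2) +
the mean of the pointwise product of those four maps (1).  The
convergence index uses the *outward* radial direction so that a dark
lesion center (gradients pointing toward brighter, i.e. outward) scores +1.
The isolated index (ring mean / ring std, width 3 outside radius 7) carries
a 1e-3 std floor — far below sensor noise — so it cannot amplify float dust
on flat rings.  Color statistics use RGB, CIE L\*u\*v\* (D65, channels
affinely mapped to [0,1] by the sRGB gamut bounds) and conical-model HSI.
Undefined statistics (empty outer ring, zero gradients) are imputed as 0.

The descriptors follow the classical layouts at patch size 31×31 (≈ 15 px
radius, covering a lesion and its surround): a Felzenszwalb-style HOG with
18 contrast-sensitive + 9 insensitive orientation channels + 4
normalization energies per cell; sign-split Haar response sums for the
SURF cells (L2-normalized); and frequency-domain log-polar Gabor transfer
functions (center frequencies 0.25/0.125/0.0625 cyc/px, one-sided) for
GIST, whose magnitudes rotate with the patch — verified by a 180° rotation
permutation test.

## Classification

Candidates with area outside [2, 150]·rho² px or minor/major axis ratio
below 0.3 are excluded outright.  The rest are scored by RUSBoost: T = 500
rounds of AdaBoost.M2 in which each round trains a depth-3 decision tree on
all positives plus an equal-size uniform random undersample of the
negatives, while the boosting weight distribution, the pseudo-loss

    eps_t = sum_i D_t(i) (1 − h_t(x_i, y_i)),   beta_t = eps_t/(1 − eps_t)

and the update `D ∝ D · beta^h_true` are maintained over the full training
set.  Rounds with pseudo-loss ≥ 0.5 are redrawn up to 10 times, then
skipped.  The score is the normalized weighted vote
`sum_t log(1/beta_t) h_t(x,1) / sum_t log(1/beta_t)` in [0, 1]; sweeping a
threshold over it generates the FROC operating points.  Training is
deterministic given the seed.

The imbalance-ordering experiment (undersampling helps) compares RUSBoost
against the *unmodified* standard boosted ensemble — discrete AdaBoost with
identical weak learners and round count, taken from scikit-learn as an
independent implementation.  The package also ships `adaboost_train`, the
same pseudo-loss loop without undersampling, as an ablation baseline; with
shallow trees its probability-weighted vote is a stronger ranker than
discrete boosting, and on cleanly separable synthetic clouds it can match
or exceed RUSBoost — the advantage of per-round undersampling shows against
the standard discrete algorithm.

## Evaluation

A finding *hits* the closest annotation if their center distance is
strictly smaller than that annotation's radius (ties on distance broken by
lower annotation index); per annotation, only the highest-scoring hit is a
true positive, every other finding is a false positive.  Sweeping all
distinct score thresholds gives the FROC curve (pooled sensitivity vs mean
FPs/image).  Sensitivity at a standard level uses the right-continuous step
convention (the last operating point with FPs/I ≤ level).  CPM is the mean
sensitivity at 1/8, 1/4, 1/2, 1, 2, 4, 8 FPs/image; the partial AUC is the
step-function area over [1/8, 8] normalized by the interval width so a
perfect detector scores 1.  A 75%-consensus helper fuses multiple expert
annotation files by greedy center clustering.

## Synthetic phantoms

The generator renders what the detector assumes about fundus images and
returns exact ground truth: smooth background (base 0.45, linear ramp
amplitude 0.1, low-frequency shading 0.05), six non-crossing quadratic
Bezier vessels with Gaussian cross-profile (half-width at half maximum
1–6 px, matching the 1–6 px caliber range the multi-scale analysis is built
for; contrast 0.08–0.18), ten Gaussian-pit lesions covering the clinical
taxonomy (4 regular, 1 subtle at contrast 0.05–0.08, 1 irregular elongated
with axis ratio ≥ 0.3, 1 clustered pair 4–8 px apart, 2 vessel-adjacent at
2–4 px from the vessel edge), about 450 unannotated faint dark specks
(contrast 0.02–0.06) emulating the background clutter that makes real
candidate sets imbalanced (the extracted candidate sets run ≈ 25 negatives
per positive), and i.i.d. Gaussian sensor noise (sigma 0.01).  Placement is
rejection-sampled; every lesion center is a strict local minimum of the
noiseless rendering, regeneration is bit-identical given (params, seed).

What the phantom does *not* emulate — and hence what green tests do not
show about real data: optic disc, fovea, exudates and hemorrhages;
JPEG-compression blur of subtle lesions; vessel crossings and calibre
changes (vessels are drawn disjoint precisely because a crossing is
blob-like to any shape-based filter — on real images crossings survive
removal and must be rejected by the classifier); non-Gaussian sensor noise;
and the full appearance diversity of true lesions.  Published benchmark
scores on the real screening databases are therefore not reproducible
here; the synthetic end-to-end CPM (≈ 0.93 over 8 test scenes at the
default conditions) is a regression baseline for the pipeline, not a
clinical claim.

`generate_candidate_dataset` emulates the classification stage in
isolation: a compact positive Gaussian cloud against a negative cloud at
433:1 (the imbalance observed on a 50-image screening training set),
separated along 10 informative coordinates of the 1247-dimensional feature
space, with an optional `contamination` fraction of negatives drawn from
the positive component (negative labels on real data are impure — missed
annotations, ambiguous multiple hits of one lesion).

## Numerical conventions

* All rasters float64 in [0, 1], normalized once on load.
* Disk supports include a pixel iff its center is within Euclidean
  distance r; supports are clipped at image borders.
* Facet and derivative convolutions use nearest-neighbor border extension;
  map convolutions (convergence, disk sums) use zero padding.
* Ray sampling for angle features rounds half-up (`floor(x + 0.5)`), which
  is translation-invariant where round-half-to-even is not.
* K is exactly rotation-covariant under 90° rotations.  Under arbitrary
  rotations covariance holds only away from ridges: K is large and sharply
  peaked on ridge flanks, and resampling interpolation perturbs the local
  gradient covariance there by O(1), so the interpolation-tolerance check
  is run on a vessel-free blob phantom.
* The segmentation update is deterministic, so one unchanged iteration
  implies convergence; evolution caps at 100 iterations.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic scenes
at the native 768×576 size: 20 scenes for extraction recovery, 6 training
+ 8 test scenes (T = 200 rounds) for the end-to-end CPM, a 65k-row
433:1 table (150 positives, T = 100, `max_features` 32, evaluated at a
2-FP-per-image-equivalent budget) for the imbalance-ordering experiment,
and 64×64 rasters for the brute-force oracle equivalences.
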