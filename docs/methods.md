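# Methods notes

This note records the models, conventions, numerical choices, and
validation designs behind `myoatlas`, in the order the pipeline runs.

## Inputs and label model

A study is a short-axis stack of segmented structures. Labels are stored as
one `uint8` bitmask volume (bit 0 myocardium, bit 1 infarct, bit 2 early
MVO, bit 3 late MVO), which makes the nesting rules — infarct ⊆ myocardium,
MVO ⊆ infarct — cheap to verify and enforce. Validation *reports* nesting
violations before clipping them, so imported data with inconsistent
segmentations is flagged rather than silently repaired.

Rasterization uses the pixel-center even-odd rule; a center lying exactly
on a polygon edge is inside (a deterministic tie-break, so identical inputs
always produce bitwise-identical volumes). Pixel coordinates are 0-based,
x = column, y = row; "anticlockwise" is defined in the displayed image
plane with y pointing up, and a chirality flag flips it for mirrored
acquisitions. Slice indices simply follow acquisition order; anatomical
direction is carried by the ordering of the apex and base (mitral-level)
indices, which are real-valued and may lie outside the acquired stack when
the annotator extrapolated them.

The CVI42 workspace parser targets the v5-style element layout (`Hash`
items, `sa*Contour` point lists, `SubpixelResolution` scaling). Unknown
contour roles are skipped with a warning, never fatally; the role map is a
module-level dict (`CVI42_ROLE_MAP`) that can be extended for other export
dialects. The package's own workspace writer produces the same dialect and
round-trips vertex-exactly.

## Myocardial coordinates

* **Radial**: r = d_endo / (d_endo + d_epi) with unsigned distances to the
  two wall boundaries. This form is contour-parameterization-free and
  monotone across the wall. When contour polygons are available they are
  rasterized directly on the oversampled grid and distances are Euclidean
  distance transforms against those fine regions; the half-pixel
  center-vs-boundary offset of the EDT is subtracted, so the residual bias
  shrinks as 1/oversample. Without polygons (e.g. bundles re-read from
  disk), masks are upsampled by linear interpolation of the indicator
  thresholded at 0.5, which places the boundary midway between opposite
  native pixel centers.
* **Circumferential**: polar angle about the cavity center (centroid of the
  endocardial contour, or of the cavity pixels in mask-only mode), offset
  so the LV-RV junction ray is c = 0, anticlockwise, periodic in [0, 1).
  An angle-based (rather than arc-length) parameterization keeps Bull's eye
  segments angle-regular and anchored at the junction.
* **Long-axis**: z = (k − apex)/(base − apex), constant per slice. Slices
  with z outside [0, 1] are excluded; no trans-slice smoothing is applied.
* The LV outflow tract is removed as the *shorter* angular interval between
  the two LVOT landmarks; exactly opposite landmarks are ambiguous and
  raise rather than guess.
* Default oversampling factor: 4 (in-plane), protecting thin walls covered
  by few pixels.

Accuracy on analytic circular annuli (the oracle): maximum absolute error
of r below 0.012 at oversample 4 on a 10-pixel wall, circumferential error
at machine precision, and a strictly decreasing error curve
(≈0.15 → 0.08 → 0.04) from oversample 1 to 4 on a 3-pixel wall.

## Reference geometry and standardization

The common target is a semi-ellipsoid: 21 slices of 80×80 px with maximal
(basal) endocardial/epicardial radii of 30/50 px. Only the basal radii,
slice count and grid are fixed by convention; the apical taper is
`R(z) = R_base · sqrt(1 − ((1−z)·a)²)` with `a` set so the apical slice
keeps 25 % of the basal radius (wall present on all 21 slices). Note that a
50 px radius exceeds the 40 px half-width of the grid, so the outer wall of
the most basal slices is clipped at the four edge midpoints (it survives
toward the corners); every downstream statistic is missing-data aware, and
the constructor refuses configurations whose epicardial radius exceeds the
grid half-diagonal. Reference slice k has z = k/(n_slices − 1).

Warping maps reference coordinates into the subject's scattered coordinate
samples. The samples are exactly coplanar per acquired slice, so the
interpolant exploits that structure: 2D scattered linear (Delaunay
barycentric) interpolation in (r, c) within each acquired plane, blended
linearly in z between the two planes bracketing the reference slice. (A
single 3D triangulation of the same samples is mathematically equivalent up
to triangulation choice but numerically hostile: coplanar inputs force
joggling and point location becomes pathologically slow.) Circumferential
periodicity is handled by duplicating samples within 0.1 of the 0/1 seam;
reference points outside a plane's convex hull fall back to the nearest
sample within 0.1 coordinate distance, beyond which they are missing.
Binary channels are interpolated as real values and **not** re-thresholded
— group averaging consumes the soft occupancy directly (a 0.5
re-binarization flag exists for sensitivity analyses). Reference slices
with z outside the subject's acquired range are missing, never
extrapolated.

## Analysis lattice and per-location statistics

Patterns are averaged into 24 (circumferential) × 21 (slice) × 20 (radial)
cells; a cell is the mean of its covered reference pixels and is missing
when none are covered. Location/transmurality maps are the max/mean over
the radial axis; variability is the across-subject SD of per-subject
transmurality. Group means flag cells observed in fewer than half the
subjects.

The two-group comparison at each (c, z) location is a two-sample Hotelling
T² on the radial-profile vector (a univariate per-cell transmurality mode
is available as a switch). The pooled covariance is inverted on its
numerical rank (eigenvalues above 1e-8 of the largest; rank also capped at
n−2), and the F transform uses that rank as the effective dimension —
necessary because near-binary occupancy data are routinely rank-deficient.
Degenerate cells (zero covariance, equal means) give p = 1; locations with
fewer than 3 complete subjects per group are missing. No multiple-testing
correction is applied; the summary statistic — percentage of locations with
p < 0.05 — must be read accordingly (it is a descriptive map-level
quantity, not a family-wise claim). Bull's eyes place the apex ring at the
center, the base outermost, segment 0 at the junction, anticlockwise;
p-values render on a log color scale.

With small groups the profile test's power degrades as the radial dimension
approaches the group size; cohort-level analyses at n ≲ 15 per arm are best
run with a coarser radial lattice (e.g. `n_r=6`) or the univariate mode.

## Global descriptors

Five per-subject descriptors, all in percent: infarct / early-MVO /
late-MVO area (lesion pixels over myocardium pixels in native mode; mean
soft occupancy over covered reference myocardium in standardized mode),
transmurality (mean per-column infarcted wall fraction over infarct-bearing
columns only), and endocardial surface area (infarct-bearing innermost
radial cells over all wall columns — a column-based surrogate chosen so the
definition is identical before and after standardization). A column or
subendocardial cell counts as "bearing" when its occupancy reaches 0.5,
which treats binary native data and soft standardized data symmetrically.
Transmurality is missing (not zero) for subjects without infarct.

Native-mode columns are binned with *mask-consistent* coordinates — derived
from the stored label masks, not from polygon-refined boundaries — because
lesions are digitized at native resolution: mixing a subpixel wall boundary
with block-upsampled lesions systematically dilutes the boundary cells by
about one percentage point of transmurality.

Subgroup comparisons use the two-sided Mann–Whitney U test (asymptotic,
tie-corrected; fully tied data returns p = 1) for continuous descriptors
and Fisher's exact test for 2×2 tables, reported as median (IQR) or
counts (%).

## Realignment and embedding

The infarct center is the occupancy-weighted circular mean of the
circumferential bin centers (phasor sum, so the 0/1 seam is handled
exactly). Realignment rotates every pattern of a territory by the integer
bin shift nearest to the circular difference between that territory's mean
center and the LAD territory's, trading at most half a bin (1/48) of
alignment for exact mass preservation (no re-interpolation). Zero-infarct
subjects cannot be realigned and are excluded from the embedding with a
warning.

t-SNE runs on flattened lattices (missing cells imputed as 0 = no lesion;
Euclidean distances) with perplexity 10, two components, PCA
initialization, and a fixed seed; an optional stability report re-runs the
embedding under different seeds and summarizes mean pairwise Procrustes
disparity. Embedding geometry is seed-dependent by nature; only
neighborhood-level statements (cluster silhouette, duplicate co-location)
are asserted anywhere.

## Synthetic cohorts

The generator emulates the *structure* of a reperfused-STEMI imaging
cohort, not its images: two arms (defaults 65/58), four culprit territories
(mix 25/20/17/61 of 123), anatomies of 17 ± 2 slices at 1.5625 mm in-plane
/ 5 mm slice spacing with about one extrapolated slice beyond the stack on
average, near-circular walls with low-order harmonic jitter, and wedge
lesions defined in the subject's own generative coordinates (guaranteeing
nesting and exact ground truth). Territory centers (LAD 0.17, LCX 0.46,
RCA 0.79 anticlockwise from an anterior junction) are a documented
convention; extents, depths and spans were set so simulated global
descriptors land in the ranges reported for such cohorts. Lesion depth
tapers cosine-like toward the wedge edges and fluctuates along the long
axis (`depth_zvar_sd`) and optionally around the circumference
(`depth_cvar_sd`) — real infarcts are not uniformly transmural. Per-subject
random streams are keyed by (master seed, subject index), so cohorts are
bitwise reproducible and extending a cohort never perturbs existing
subjects.

What the generator does **not** emulate: image intensities and their noise,
papillary muscles and trabeculation, true coronary perfusion territories,
breath-hold misregistration between slices, and segmentation ambiguity
beyond simple contour jitter / label flips. Passing tests therefore
demonstrate correctness of the *pipeline mathematics* under known truth,
not robustness to every failure mode of real segmentations.

## Validation experiment design

The validation suite (`myoatlas.validation`, asserted in the test suite and
recomputed by `scripts/acceptance.py`) runs at reduced problem sizes chosen
to keep desk-top runtimes while preserving statistical meaning; the
cohort-level studies use a miniature reference (11 slices of 44×44, radii
12/19), oversampling 1–2, and coarse radial lattices (3–6 bins).

* **Permutation oracle.** The F-transformed Hotelling p-value is compared
  with a 20,000-draw label-permutation estimate on 20 Gaussian instances of
  24 + 24 subjects with 3 features, within 3 Monte-Carlo standard errors
  per instance. The instance size matters: the conditional
  F-vs-exact-permutation discrepancy shrinks roughly as 1/n and at 8 + 8
  subjects it exceeds the Monte-Carlo resolution of any feasible draw
  count, so agreement is asserted at a size where the oracle's own noise is
  the binding error. The permutation statistic is computed from batched
  sums and cross-products, independent of the pipeline's implementation.
* **Type-I error.** 24 independent null cohorts of 30 + 30 subjects whose
  arms share one generator; the per-location rejection rate at α = 0.05 is
  pooled over all tested locations (≈5,200 cells) and must lie in
  [0.03, 0.07]. A binomial band of that width presumes nearly independent
  replicates, which dictates the calibration phantom: lesions cover most of
  the circumference (so occupancy varies continuously at nearly every cell
  rather than being zero-inflated, where any location test is conservative)
  and transmural depth varies as a spatially decorrelated field with a
  small global component (so a chance arm imbalance in one subject-level
  parameter does not shift every location coherently). Sparse, realistic
  lesion phantoms give strictly *conservative* per-location behavior
  (rates ≈ 0.02), which is the safe direction but not a calibration
  measurement.
* **Effect recovery.** 60 + 60 subjects, +0.2 transmural depth injected
  over a known circumferential/long-axis window; the p < 0.05 region must
  overlap the injected window with Dice ≥ 0.5.
* **Analytic anchors.** Coordinate and warp accuracy on circular annuli;
  the quarter-wedge phantom (extent 25 %, depth 60 %, half the slices)
  whose descriptors are the products 7.5 % / 60 % / 12.5 % up to
  digitization (the measured pixel-count area is ≈7.3 % because an annular
  sector's area slightly under-represents its radial fraction even on a
  thin wall).

## Known limitations

* Single-observer landmarks: the junction and apex/base annotations enter
  as given; the reproducibility tooling quantifies their impact but the
  pipeline does not model annotation uncertainty.
* The endocardial-surface and transmurality definitions are column-based
  operationalizations; other software may use contour-length-based
  variants, which will not agree exactly.
* The per-location Hotelling p-values are raw; spatial correlation between
  neighboring cells and multiplicity are left to the reader (cluster-based
  permutation inference would be the natural extension).
* Standardization distorts global descriptors slightly (partial-volume
  softening and the no-extrapolation coverage rule); on fully covered
  synthetic subjects native and standardized descriptors agree within 15 %
  relative, with the largest discrepancies for sharp lesion boundaries
  falling between reference slices.
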