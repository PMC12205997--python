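# Methods

## Coarse-graining

A hemisphere is represented by a closed, outward-oriented pial/white
triangle-mesh pair. At cut-off scale λ the pair is converted to an
axis-aligned voxel grid of side length λ: a voxel is white matter if its
center lies inside the white surface, gray matter if inside the pial
surface but not white, background otherwise. The grid is aligned to the
pial bounding box expanded by one voxel, with the origin snapped to a
multiple of λ so that re-runs — and rigid translations by multiples of λ —
reproduce the same grid. Grid placement still induces O(λ) jitter in the
metrics for general translations; tests and documented tolerances account
for this, and a user-supplied fixed origin is available.

**Point-in-mesh test.** Voxel centers are classified by exact column
ray-parity: triangles are binned by their xy bounding boxes, each (x, y)
voxel column intersects its candidate triangles via 2-D barycentric
coordinates, and voxels between successive crossings are inside. Columns
where the line grazes a triangle boundary within 1e-9 (barycentric), hits
a projectively degenerate (vertical) triangle's segment, or collects an
odd number of crossings are re-resolved voxel-by-voxel with the
generalized winding number (Van Oosterom–Strackee solid angles), which is
robust for any watertight mesh. The two routes agree bit-for-bit on every
fixture in the test suite; the winding number also serves there as an
independent oracle for the production path.

**Surface re-extraction.** Coarse-grained surfaces are marching-cubes
isosurfaces at level 0.5 of the tissue indicator (gray∪white for the pial
surface, white alone for the white surface) on the zero-padded grid, with
vertices mapped to mm via voxel centers. The binary indicator is
anti-aliased with a Gaussian of σ = 0.8 voxels before surfacing. The σ
default matters: raw binary marching cubes overestimates the area of a
ball (R = 30 mm, λ = 0.5 mm) by 8.7% through stair-step faceting, while
heavy smoothing (σ = 1) shrinks curvature so strongly at the coarsest
ladder scales that the surface becomes effectively convex and the convex
hull's area can exceed the mesh area by tenths of a percent through
saddle-spanning. σ = 0.8 keeps the ball-area bias at 0.55% and preserves
a strict hull-below-pial margin (≥ 0.7%) across the whole ladder; both
properties are enforced against closed forms in the test suite. σ is
configurable and σ = 0 recovers the literal binary variant. Extracted
surfaces are closed by construction and re-oriented outward by the sign
of the divergence-theorem volume.

**Exposed surfaces.** The hemisphere exposed area `A_e(λ)` defaults to the
area of the convex hull of the coarse pial surface (triangulated Qhull
output, faces oriented by the hull's outward plane equations). The
gyrification-index-style alternative — morphological closing of the
gray∪white mask with a ball of 15 mm diameter, then isosurfacing — is
implemented and selectable (`ae_mode="closing"`), and is the surface used
for lobe-level exposed areas when those are requested. The closing uses
the discrete ball of radius ⌈(d/2)/λ⌉ voxels (rounding up, so the element
is never smaller than the physical ball; a diameter below λ degenerates
to a single voxel and is the identity). Dilation and erosion are computed
with Euclidean distance transforms, which is exactly equivalent to the
explicit structuring element (verified against `scipy.ndimage.binary_closing`
in tests) and fast even when the ball spans ~24 voxels at λ = 0.32.

## Metrics

Hemisphere level: `A_t` is the triangle-area sum of the coarse pial
surface, `A_e` the hull (or closing) area, `V_GM = (#GM voxels)·λ³`, and
`T = V_GM / A_t`. The "native" entry uses the input meshes directly:
`A_t = area(pial)`, `V_GM = volume(pial) − volume(white)` by the
divergence theorem, `T = V_GM / A_t`. Note this native thickness
definition is chosen for consistency with the coarse-grained ratio
definition; surface-reconstruction toolchains report vertex-wise
thickness instead, which differs.

Lobe level: coarse-surface vertices inherit the label of the nearest
original-surface vertex (KD-tree; exact ties resolved by the tree's
deterministic ordering). Triangles are assigned to the majority label of
their three vertices, three-way ties to the lowest region code, so region
areas partition the mesh area exactly. Lobe thickness is the mean over
the lobe's pial vertices of the exact point-to-triangle distance to the
white surface (projection with edge/vertex clamping; candidates pruned by
a centroid KD-tree with the nearest-vertex distance as a provably safe
radius bound, processed in bounded-memory chunks). The insula's area is
split into the frontal, parietal and temporal lobes proportionally to
their areas; its thickness enters the recipients through the
transferred-area-share weighted mean, which conserves both the total area
and the area-weighted mean thickness of the five-region set to machine
precision (asserted in tests).

## Synthetic geometries

The generator triangulates a subdivided icosahedron and modulates the
radius as `r(θ, φ) = R + a·sin(mθ)·sin(mφ)`; the white surface is the
same mesh with radius reduced by t. A separable sinusoid was preferred
over spherical harmonics because it has a single unambiguous dominant
arc-wavelength, `2πR/m`, giving one knob for "feature size"; the radial
(not normal) offset for the white surface avoids self-intersection at
high fold amplitude and makes the radial thickness exactly t (tests allow
2% for the min-distance estimate). With a = 0 the pair is two concentric
spheres whose area, volume and thickness have closed forms — these anchor
every downstream geometric operator. Quadrant labels (four azimuthal
sectors plus a 25° polar cap standing in for the insula, < 10% of
vertices) exercise the lobe pipeline.

Default study geometry: R = 30 mm, t = 2.5 mm, folds a = 3 mm, m = 12
(arc-wavelength ≈ 15.7 mm), icosphere subdivision 4 (5,120 faces,
~2.1 mm edges — an order of magnitude below the fold wavelength). These
sizes keep a full 15-scale ladder sweep at roughly a minute while leaving
the fold wavelength well inside the resolved regime.

## Synthetic cohorts

A cohort row is (subject, age, sex, site, metric@scale ...). Each metric
is mean-trajectory(age) + site offset + sex offset + shared component +
independent noise, all additive on the (log10) metric scale, deterministic
given the seed. The default "lifespan" preset has n = 800, ages uniform
on [6, 88], two sites, and:

* `At@native` (log10 mm²): linear decline, ~16% total over the age range;
* `At@1.86`: linear rise, ~25% total;
* `T@{0.32,0.71,1.86,3.02}` (log10 mm): declining curves with a steep
  exponential childhood component plus a linear adult component; baseline
  offsets increase with scale (2.5 → 4.2 mm) and total declines grow with
  scale (35% → 55%) but are capped so the scale ordering never crosses at
  any age.

The two area metrics share one standard-normal component per subject with
opposite age-direction loadings. In age-equivalent units the shared
variance is 560 y² and the independent variance 480 y² per scale, against
an age variance of 82²/12 = 560 y²: a single-scale age model can explain
at most 560/1600 ≈ 35% of age variance, while a model using both scales
cancels the shared component and reaches ≈ 560/800 = 70%. This is the
generative embodiment of "different scales carry complementary
information", and it is what the brain-age comparison measures.

What the preset does *not* emulate: measurement artifacts, non-Gaussian
site effects, age-dependent sampling imbalance, hemispheric asymmetry, or
any mechanistic link between the cohort tables and the synthetic
geometries. Passing tests therefore demonstrate that the estimators
recover the structure they model, not that real cortices have it.

## Normative trajectory model

For one metric column the model is a four-parameter family whose every
parameter depends on age through a cubic P-spline (20 equally spaced
basis functions on [6, 88], second-order difference penalty). The default
family is the Box–Cox power exponential — location μ (log link), scale σ
(log), skew ν (identity), kurtosis τ (log), with the usual truncation to
positive responses; a plain Gaussian location-scale family is available
as a fallback. Site enters as ridge-penalized additive offsets on the μ
and log σ predictors (shrinkage standing in for mean/variance random
effects; with two sites and n in the hundreds the shrinkage limit
coincides with fixed effects), sex as ±½-coded offsets on μ, log σ and ν.

Fitting is penalized maximum likelihood by cyclic backfitting: for each
distribution parameter in turn, per-observation score and curvature with
respect to that parameter's linear predictor are computed by central
finite differences of the log-likelihood (curvatures floored at the
squared score when non-positive), a penalized weighted least-squares step
updates the coefficients, and step-halving enforces a monotone penalized
deviance (asserted to 1e-6 in tests). Convergence is an absolute deviance
change below 1e-3 (default) within 200 outer iterations; non-convergence
is flagged on the model object and warned, never silent. The μ smoothing
parameter is selected on a log grid (0.1 … 1e5) by generalized AIC with
dof penalty k = log n (the SBC-like choice; k configurable) — with k = 2
the null-data fit keeps visible wiggle; σ, ν, τ default to fixed heavier
penalties (50, 200, 200). Note the second-order penalty's null space is a
straight line, so even at maximal smoothing a pure-noise metric retains
the sampling slope of a line fit (~se(slope)·range(age)); the null-data
test bounds the fitted median's range at a quarter of the noise SD
accordingly.

Population quantile curves marginalize sex by averaging the two
sex-specific distribution-parameter sets with the training-cohort
proportions, at zero site offset. Deviation scores are randomized-quantile
style residuals `Φ⁻¹(F(y | age, sex, site))`; subjects from unseen sites
are scored with zero site offset and flagged. Models serialize to JSON
(family, knots, coefficients, offsets, convergence record) and round-trip
exactly.

## Brain-age models

Three additive Gaussian models predict age: a smooth of `At@native`, a
smooth of `At@1.86`, or both, each plus fixed effects of sex and site
(reference-coded; a single-level factor is dropped with a warning). The
smooths are penalized B-splines with basis dimension 10; smoothing
parameters minimize GCV (deterministic Nelder–Mead search; statsmodels'
default global optimizer draws from the process-global RNG and is
avoided). Adjusted R² = 1 − (1 − R²)(n − 1)/(n − edf − 1) uses the
model's total effective degrees of freedom, not the raw parameter count.
The bootstrap resamples subjects with replacement, refits every model per
replicate with the full-data smoothing parameters held fixed, and is
bit-reproducible given the seed; replicates that lose a factor level are
flagged and recorded as missing. A perfectly noiseless response makes the
underlying IRLS degenerate, so the fitter retries once with a 1e-8-scale
deterministic dither — relevant only to the perfect-fit limit. No
prediction-bias ("regression to the mean") correction is applied, by
design; with noisy predictors the predicted-vs-actual slope sits strictly
between 0 and 1.

## Numerical and degenerate-input policy

* Readers reject dialect violations (wrong magic bytes, truncation, label
  counts that do not match the mesh) instead of guessing; writers refuse
  empty meshes. The FreeSurfer `.annot` writer emits an old-style
  colortable; codes are renumbered to colortable order on read, so exact
  label round-trips hold for contiguous 0-based codes (which the package's
  generators produce).
* Meshes flagged closed must have every directed edge paired with its
  reverse exactly once and positive signed volume.
* A scale larger than the mesh bounding box raises a degenerate-grid
  error; an empty tissue selection and a coplanar hull input are errors;
  an empty label region yields an absent (not zero) thickness.
* All randomness flows through explicitly seeded generators; sweeps,
  fits and bootstraps are deterministic given data, config and seed.

## Known limitations

* Metrics carry O(λ) grid-placement jitter for arbitrary rigid motions;
  only translations by multiples of λ are exactly invariant.
* The coarse-graining cannot recover surface buried between touching
  fold walls at any λ; the native entry is the only fold-complete value.
* Fold removal is not a sharp threshold in λ/w: its onset also depends on
  the fold amplitude relative to the voxel size, and for λ well beyond the
  fold wavelength the grid becomes so coarse (few voxels across the whole
  object) that discretization error dominates the smooth-envelope limit.
* The location-scale-shape fitter is a from-scratch implementation
  aimed at the recovery properties tested here; it does not reproduce any
  particular reference implementation's coefficients, and its random
  effects are ridge approximations rather than integrated likelihoods.
* Lobe-level exposed area is computed from the closing surface and is
  comparatively slow at the smallest scales; it is off by default.
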