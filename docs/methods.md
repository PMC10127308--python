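# Methods

This note records the model, the numerical choices, and what the synthetic
phantom does and does not show about real data.  Lengths are in μm
throughout; angles in degrees unless noted.

## Coordinate conventions

Arrays are indexed (i, j, k) along world (x, y, z); the world coordinate of
voxel (i, j, k) is `origin + voxel_size · (i, j, k)`, voxels isotropic,
0-based indices, voxel centres at integer multiples of the voxel size.  TIFF
stacks are slice-major (z, y, x) on disk; the transpose happens only at I/O.
All geometry is computed in world μm; intensities are floats internally
regardless of on-disk bit depth.

## Alignment and surface model

The global frame is the PCA of the cornea surface voxels: rows of the
rotation are principal axes in descending-variance order; the third axis is
signed so that a user-supplied interior reference point (we use the eye-label
centroid) has positive z′, i.e. z′ grows from the outside of the eye inward;
the first axis is signed to make the frame right-handed.  Degenerate
(collinear) clouds are rejected.

Sub-region frames take one liberty beyond plain PCA: their in-plane rotation
is locked to the parent frame's x′ axis (the first two axes are replaced by
the projection of x′ onto the local surface plane and its right-handed
completion).  Plain PCA leaves that rotation arbitrary per sub-region, and
the patch dictionary is orientation-sensitive — its patches span neighbouring
lattice discs — so with arbitrary in-plane rotations a dictionary trained on
one sub-region does not transfer to the others.  The surface-normal direction
(the meaningful part of the local PCA) is unchanged.

`poly55` means all 21 monomials x^i y^j with i + j ≤ 5.  (x, y) are centred
and scaled to unit standard deviation before fitting, purely for
conditioning; the normalization is stored with the coefficients.  The fit is
linear least squares (`lstsq`); rank deficiency triggers a warning and the
minimum-norm solution.  The fit reproduces any polynomial of total degree
≤ 5 to machine precision; its rmse is the root-mean-square z residual in μm.

The sub-region grid divides the (x′, y′) bounding box into r × c rectangles
with r·c = N_SR, choosing the factor pair whose cell aspect ratio is closest
to the bounding box's (on a log scale) and placing the larger factor along
the longer side.  Rectangles are expanded by the overlap (default 20 μm, one
expected cone spacing) so border cones are never lost; cones detected twice
in an overlap are resolved by the final de-duplication stage.

## Unfolding

The fitted surface is resampled at `uv_spacing`; normals are the analytic
(−∂f/∂x, −∂f/∂y, 1), normalized, interior-pointing by the +z′ convention.
Depth samples run over `depth_range` (default 0–120 μm, covering cornea plus
cone layer; configurable because the span varies by species).  Intensities
are sampled with cubic-spline ("tricubic") interpolation of the whole
volume; a trilinear fallback (`interpolation_order: 1`) exists for
memory-constrained runs.  The exact (u, v, w) → world map is stored with the
unfolded block, so the back-transformation is a table lookup plus
nearest-voxel rounding — never a re-derivation.  On collision, foreground
wins over background and the lower cone id wins ties; out-of-volume targets
are dropped and counted.

Two defaults here differ from the obvious 1:1 choice, both set during method
development on phantoms:

* **Sampling density** is half a voxel in (u, v) and w.  With 1:1 sampling,
  nearest-voxel rounding of the unfolded grid leaves unfilled scan voxels
  wherever the surface is tilted; under the 6-connectivity used for
  component analysis these holes split single cones into fragments and
  end-to-end recovery collapsed from ~92% to ~52%.  2× oversampling closes
  the holes at 8× the sampling cost, which is still seconds per sub-region
  at phantom scale.
* **Footprint masking**: unfolded columns farther than 1.5 voxels (in the
  local (x, y) plane) from any cornea voxel are discarded.  A sub-region's
  rectangle is the bounding box of a curved patch, so its corners lie
  outside the data; there the polynomial extrapolates wildly and the
  extrapolated columns can back-map into the volume interior on top of
  genuine cones.

## Texture segmentation

The dictionary clusters all M×M patches of the training slice
(mean-subtracted per patch, for robustness to slow intensity drift) with
mini-batch k-means, K clusters, fixed seed.  Label propagation is the
two-step accumulate/project scheme: annotated pixel labels are averaged into
per-(cluster, within-patch-position) class weights through each pixel's
patch memberships, projected back to dense per-pixel probabilities, and
accumulated once more; weights are normalized per position, and positions
never observed fall back to an uninformative 0.5/0.5.  This flat-k-means,
two-step variant is one of several published propagation schemes and is a
deliberate substitution point.  Probabilities are proper (non-negative, sum
to one) by construction; segmentation thresholds the cone-class probability.

Class defaults are M = 9, K = 1000 (K is capped at the patch count).  The
pipeline configuration defaults to M = 5 and a threshold of 0.6 instead:
at the 4 μm working resolution a 5-pixel patch spans ≈ 20 μm — one
ommatidial spacing, i.e. one repeating texture unit — which segments the
2–3-pixel cone discs markedly better than larger patches (voxel F1 0.84 vs
0.69 at M = 9); and at a 0.5 threshold the dictionary's one-pixel
probability bleed bridges neighbouring discs where the lattice is densest,
merging cones into single components.  Users working at other resolutions
should scale M to roughly one lattice period.  The interactive annotation
loop is replaced by a supplied annotation image, so everything runs
headless; a trained dictionary serializes to a single `.npz` and is
reusable across sub-volumes and specimens.

## Post-processing cascade

Components use 6-connectivity — the conservative choice, since fused
neighbour cones are the main failure mode.  Per-cone characteristics come
from the voxel PCA: the axis is the leading eigenvector, signed toward the
nearest cornea point; length is the extent of projections on the axis and
radius the mean half-extent on the two minor axes (extent-based rather than
eigenvalue-scaled — parameter-free and directly testable; a substitution
point).  The neighbour distance is the mean of the three nearest
centre-to-centre distances.

Stages, in order:

1. **Size**: components with fewer than 10 voxels are removed (strictly
   fewer; a 10-voxel cone survives).
2. **GMM/AIC**: per sub-region, cone-centre z is fitted as poly55 of (x, y)
   in the sub-region frame; 1–3-component 1-D Gaussian mixtures are fitted
   to the signed residuals and the best-AIC model selected.  Automatic
   validation keeps the largest component plus any component whose mean is
   within 2 μm of it; an interactive mode substitutes the user's choice.
   Sub-regions with fewer than 21 cones pass through (the surface fit would
   be under-determined).  GMM non-convergence falls back to one component.
3. **Outlier screens**: in the full-cornea frame, five poly55 fits of (x, y)
   → {z-scored centre z, size, length, radius, neighbour distance}.  A cone
   exceeding k·MAD (k = 4; MAD scaled by 1.4826 for consistency with the
   normal σ) in any field is removed.  Because a gross outlier drags the
   non-robust fit, flagged points are excluded once and everything is
   re-screened against the refit.  Near-zero MADs (field exactly polynomial)
   skip that screen.  The screens are invariant to affine scaling of a
   field, so whether a field is "normalised" first is immaterial.
4. **De-duplication**: centres are projected to a final poly55 surface
   ("fitted centres"), single-linkage clustered, and clusters cut at the
   13 μm cut-off; within each cluster the member with the largest fitting
   residual *among those in a violating pair* is removed iteratively until
   all survivors are farther apart than the cut-off.  (Restricting removal
   to violating members keeps an innocent third cone 14 μm away untouched.)
   With fewer than 21 cones the raw centres stand in for fitted ones and
   the residual is the deviation from the median z.

Every raw cone ends in exactly one status; counts are conserved and logged
in the elimination report.

## Metrics

* Surface modelling error: unweighted mean of per-sub-region rmse.
* Predicted ommatidium count: the 0.5-isosurface of the cornea label is
  meshed after Gaussian smoothing (σ = 1 voxel; a raw binary staircase
  overestimates area by tens of percent).  The label is a thin shell, so the
  mesh covers both faces and the area is halved.  Facet areas use the
  regular-hexagon formula (√3/2)·d² from the flat-to-flat diameter; they are
  interpolated at triangle centroids (linear in the samples' principal
  plane, nearest-neighbour outside the hull) and averaged with
  triangle-area weights.
* Duplicate matching is greedy nearest-first, one-to-one, at a centre
  distance below one voxel; α = arccos of the dot product of the paired
  axes, both oriented toward the cornea, reported in [0°, 180°] without
  folding.
* Density ratio R: sampling points come from deterministic farthest-point
  sampling over the cornea surface voxels (default 200 points); R is the
  cone count within 100 μm over the locally expected count (local mesh area
  over local mean facet area), clamped to [0, 1].

## Phantom

The phantom emulates the pipeline's inputs at a typical micro-CT working
resolution of 4 μm/voxel: a spherical-cap cornea shell (default radius
300 μm, half-angle 60°, thickness 10 μm), cone frusta (length 40 μm, radii
5 → 2.5 μm) starting 10 μm beneath the external surface, one per site of a
20 μm hexagonal lattice mapped onto the cap with a Lambert equal-area
projection — the projection preserves lattice density everywhere on the cap
(spacing distortion stays within ±15% at a 60° rim and < 2% near the apex,
where the surface spacing is 20 ± 0.5 μm).  The lattice keeps a 5° margin
off the cap rim so every frustum is fully contained.  Cone axes follow the
inward surface normal tilted meridionally by a skew growing linearly from 0°
at the apex to `skew_max` (default 10°) at the rim, as observed in bee eyes.
Intensities (background 20, matrix 80, cone 160, cornea 200) give a
cone/matrix contrast of 80; the default noise σ = 8 is 10% of that
contrast.  Ring artefacts are additive concentric sinusoids per slice.
Rasterized cone radii are floored at 0.75 voxel so thin tips stay
6-connected, and rasterization never invades the cornea shell.  The truth
table stores centres (frustum midpoints — note these sit deeper than the
surface lattice, so their spacing is contracted by (R − 30)/R), unit axes
oriented toward the cornea, lengths, radii and lattice indices.
`degrade_phantom` deletes cones (optionally in one hemisphere) and injects
sub-threshold bright blobs kept clear of cones, for stress-testing the
filters and the density ratio.

What the phantom does *not* emulate: partial-volume blur and detector PSF,
beam hardening, staining gradients, cornea thickness variation, non-frustum
cone shapes, fused cone bundles, and elongated (non-spherical) eye outlines.
Passing tests therefore demonstrate the geometric and statistical machinery
— unfolding fidelity, dictionary propagation, cascade behaviour — not
robustness to every real-scan artefact.

## Problem sizes and experiment design

The default end-to-end run (phantom of ~685 cones, volume 142×142×53 at
4 μm, 9 sub-regions) takes about a minute on one CPU and recovers 92–94% of
true cones with a mean axis discrepancy of ~2.2° across seeds.  Nine
sub-regions suit this strongly curved cap: with 4, the per-sub-region
centre-surface fits deviate systematically near the rim and the GMM stage
discards genuine rim cones.

The sub-region experiment compares N_SR = 1 against 4 on a *hemispherical*
phantom (radius 200 μm, cap 90°).  Spherical caps much below 90° are still
fit acceptably by a single global poly55 — the failure the subdivision cures
only appears when the rim becomes near-vertical, which is also where real
elongated or hemispherical eyes break a single fit.  On that phantom the
percentage of segmented cones rises from ~61% (N_SR = 1) to ~71%
(N_SR = 4).

## Known limitations

* The GMM auto-validation tolerance (2 μm) presumes residual lobes of
  genuine cones are tighter than the artefact offsets; data with a very
  rough cornea may need the interactive mode.
* Fused cone bundles are not split (no morphological post-processing); they
  survive or die as single components.
* The unfolding is a normal-projection map, not area-preserving; metrics
  that integrate over (u, v) should be computed in world coordinates, as
  the package does.
* `match_duplicates` at < 1 voxel is strict when reference centres come from
  an independent definition of "centre" (e.g. frustum midpoints); the
  matched subset is then biased toward well-recovered cones, which is the
  intended use (axis comparison among confident duplicates).
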