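# Methods

This note records the models, numerical choices, and open design decisions
behind `plantnerf`, and what the synthetic test scenes do and do not
demonstrate about real captures.

## Acquisition model and coordinate conventions

The package assumes a "camera-to-plant" orbital rig: two cameras on
horizontal circular rails of radius `r_real`, the lower one `h1` above the
ground, the upper one `h2` below the top of the camera bracket. These three
numbers are the *trajectory prior*; they are rig measurements, recorded once
at capture time, and they are what makes the reconstruction metric.

World coordinates are z-up, in meters, with the plant centered at the origin
after calibration. Camera frames follow the OpenCV/COLMAP convention
(+x right, +y down, +z optical axis); SfM text models store world-to-camera
poses, and the camera center is `−Rᵀt`. Images are undistorted once at
ingest with the Brown–Conrady model (k1, k2, k3, p1, p2); every later stage
assumes an ideal pinhole.

## Keyframe extraction

Sharpness is the variance of an 8-neighborhood Laplacian
(`[[1,1,1],[1,−8,1],[1,1,1]]`, replicate border padding) of the BT.601
grayscale image. Choices the scoring rule does not itself fix:

* Equidistant downsampling selects `round(linspace(0, n−1, target))` — an
  endpoint-covering, maximal-gap progression; fewer frames than the target
  is an error rather than silent duplication.
* The 20%-of-mean rejection threshold uses the mean over *all* frames of
  both views, computed once (single pass, not iterated re-thresholding).
* The quality gate (more than 10 rejected frames) raises an error that asks
  for re-acquisition; it never silently degrades the selection.
* The final 45-per-view subselection is a seeded uniform draw without
  replacement; output ordering is (view, source index), so reruns with one
  seed are bit-identical.

## Global pose calibration

SfM poses are defined only up to a similarity. The calibration recovers it
from the rig geometry in closed form, in four deterministic steps: total
least squares plane fit (SVD of the centered camera centers; degenerate if
the second singular value vanishes), Rodrigues rotation of the fitted normal
onto +z (the antiparallel normal rotates by π about x; the normal's sign is
fixed to a non-negative z-component), an algebraic Kåsa circle fit of the
rotated centers' XY projection (linear least squares; geometric refinement
adds nothing at realistic noise levels, and the closed form is
deterministic), and a ring split at the midpoint of the z-range with the
recentering translation `t_s = (k·x_c, k·y_c, (z_up+z_low)/2)`. The circle
center is fitted before scaling, so its x, y components are multiplied by
`k` to live in post-scale coordinates.

One degree of freedom is not observable from a circular trajectory: the
azimuth about the plant axis. It is left unfixed; plant height, ring radii
and all pairwise distances are azimuth-invariant, and tests compare only
such gauge-invariant quantities.

The plant ROI is the box `[−r_real, r_real]² × [z_low − h1, z_up + h2]`:
horizontally the rings enclose the plant, vertically it spans from the
ground to the bracket top.

## Radiance field

The scene is `F(x, d) → (c, σ)` with:

* **Position encoding**: multi-resolution hash grids, 16 levels, 2 features
  per entry, table size 2^19, resolutions in geometric progression
  `N_l = ⌊16·b^l⌋` from 16 to a 2048³ finest virtual grid. Levels whose
  dense grid fits the table are indexed directly, finer ones through the
  XOR-of-primes spatial hash. Features are trilinearly interpolated and
  concatenated (32 dims).
* **Density branch**: one hidden layer (default 64 units, ReLU), emitting a
  raw density and a 15-dim geometric feature (ELU). Density uses an
  *exponential* activation: with a softplus the learned surface density
  stalls near the level where rays are already opaque (≈30 m⁻¹), which is
  too close to any sensible mesh iso-level; the exponential's multiplicative
  dynamics reach unambiguous surface densities within a small iteration
  budget. Raw values are clamped at 8 (σ ≤ ~3×10³ m⁻¹) for safety.
* **Color branch**: the 16-dim geometric feature (raw density ‖ 15
  features — the 16th component is the raw density, the one assembly
  consistent with both branch widths) concatenated with a 4-frequency
  sin/cos encoding of the view direction (27 dims), through two hidden
  layers to a sigmoid RGB.
* **Coarse field**: a separate small field (8 hash levels to 512, one hidden
  layer) that guides hierarchical sampling. It emits a view-independent RGB
  alongside density so it can be trained by the same photometric loss —
  without a color head no gradient would reach it at all, because the fine
  samples it produces are drawn through a non-differentiable
  inverse-transform step.
* **Per-image parameters**: an exposure rate `E_i` (applied as
  `S_i = 2^{E_i}` to the synthesized color before the loss; canonical
  renders use E = 0) and an SE(3) offset (translation plus axis-angle
  rotation, applied on the left of the camera-to-world pose).
* **Background**: residual transmittance is composited onto a learnable
  global background color (sigmoid-parameterized). Scenes with a structured
  background are represented as far-field density plus this mean color.

Hash coordinates are normalized over the ROI box dilated by the maximum ray
length `t_b`, so every reachable sample point — including background
samples beyond the ROI — has a well-defined, non-clamped encoding.

## Ray sampling and rendering

Rays are clipped to the ROI with the slab test; since the cameras sit inside
the ROI box by construction, the near intersection is clamped to 0. Of the
`N_c` coarse samples, 75% are stratified over `(0, t_max]` and the rest over
`(t_max, t_b]` (`t_b` = 2 × ROI diagonal); rays that miss the box get
background-only sampling. Coarse weights
`ω_i = T_i(1 − e^{−σ_i δ_i})`, normalized over the ray, define the
piecewise-constant PDF for `N_f` inverse-transform fine samples, which are
merged (sorted) with the coarse ones for the fine pass. The last sampling
bin is closed at `t_b`, so the telescoping identity
`Σω_i + T_residual = 1` holds exactly. When every weight is zero the PDF
falls back to uniform (flagged on the batch).

Compositing is standard emission–absorption with the residual transmittance
onto the background color. Deterministic rendering (`render_view`) disables
all jitter (stratum midpoints, stratified inverse-CDF positions), so renders
are bit-reproducible.

## Training

The loss is the mean squared error between exposure-adjusted rendered and
observed colors, summed over the coarse and fine renders, plus
`λ_E Σ E_i²` and `λ_p Σ(|Δt_i|² + |Δθ_i|²)` (both λ = 1e-4). All gradients
are hand-derived: through the compositor (via suffix sums), the MLPs, the
trilinear hash interpolation (scatter-add to tables, analytic weight
derivatives to positions), the direction encoding, the ray normalization,
and the rotation offsets (right-Jacobian of SO(3)). Sample t-values are
treated as constants of each iteration (sampling is not differentiated
through), which keeps the loss smooth in the parameters; a finite-difference
check on a small ray batch verifies every parameter group.

Optimization is Adam (β = 0.9/0.99, ε = 1e-15) with per-group learning
rates: 1e-2 for hash tables, 1e-3 for MLPs, 5e-2 for exposures and the
background, 2e-4 for pose offsets. Two of these deserve their rationale:

* The exposure rate runs on a *faster* time-scale than the color MLP: both
  can explain per-image brightness, and if `E_i` adapts slowly the
  view-dependent color absorbs the differences first (measured on synthetic
  data: correlation with injected exposures 0.77–0.90 with a slow `E_i`,
  ≥ 0.99 with the fast one).
* Pose offsets run on a *slower* time-scale than everything else: once the
  poses are correct their gradients are mostly minibatch noise, and under
  Adam's normalized steps the offsets random-walk ~lr·√iters (at lr 1e-3
  that is several centimeters over a run, visibly smearing surfaces), while
  genuine corrections accumulate ~lr·iters and are still recovered at
  degree/centimeter scale.

An optional per-ray total-opacity penalty (`lambda_sparsity`, default 0)
prefers empty space over background-colored fog; it is off by default
because its gradient carries the residual transmittance and is therefore
blind behind anything already opaque, and it measured no benefit on the
synthetic scenes.

A non-finite loss aborts with the iteration number and exposure range in
the message. The parameters are float32 (float64 available for gradient
checking); the hash kernels are numba-compiled, single-threaded.

## Mesh extraction and phenotypes

Density is sampled on a regular grid over the ROI box; voxels outside the
box's inscribed cylinder are zeroed (the cameras never constrain the box
corners), and Marching Cubes extracts the isosurface at `sigma_threshold`
(default 50 m⁻¹ — the midpoint between empty space and the synthetic solid
density of 100 m⁻¹, i.e. the occupancy-0.5 analogue; real scenes may need a
different level, which is why it is config-exposed). Vertices are metric, so
plant height is the z-extent of the mesh. Optional vertex colors query the
color branch along the outward normal.

PSNR uses MAX = 1.0 on float images and 255 after 8-bit export; both are
supported and the convention is reported with the value. Identical images
report +∞.

## The synthetic scene: what it shows and what it does not

`scene_sim` builds an analytic plant — a trunk cylinder (radius 4.5 cm,
height 0.80 m, the exact recorded plant height) plus ellipsoidal leaves
constrained strictly below the apex — with piecewise-constant density
(100 m⁻¹) and distinct per-organ colors, on a constant background
(≤ 0.5 in every channel so a +1-stop exposure never saturates). Cameras
follow the rig geometry (r = 0.75 m, rings at 0.55 m and 1.05 m), with aim
heights chosen so each ring's field of view covers the entire plant, as the
physical acquisition protocol requires; without that coverage the plant
apex is visible only against itself and its height becomes ambiguous up to
the visual-hull cone of the trunk cap (≈ r_trunk · tan(elevation)).
Ground-truth images come from dense midpoint quadrature of the rendering
integral inside the plant's bounding cylinder — code fully independent of
the trained renderer, which makes it a usable oracle for compositing
(agreement to 1e-2 at matched sampling) and for closed-form slab tests.

Passing on this scene demonstrates the geometry/optimization machinery:
metric recovery through an arbitrary similarity, exposure and pose
recovery, hierarchical sampling correctness, and metric mesh accuracy. It
does **not** demonstrate robustness to real-world effects the generator
omits: textured/cluttered backgrounds, specularity and subsurface
scattering of leaves, motion blur and rolling shutter, SfM failure modes,
or wind-induced non-rigidity.

## Problem sizes

The package's own validation runs are sized for a single CPU core: training
uses 40 views at 64×64 pixels, 2000 iterations, 384 rays per batch with
24 coarse + 40 fine samples, and a 2^15-entry fine hash table; the
exposure-recovery run uses 24 views at 48×48 for 800 iterations; meshes are
extracted at grid resolution 128. The defaults in the config objects
(table size 2^19, 64-unit MLPs, 64 + 128 samples) are the intended
full-scale settings for real captures.

## Known limitations

* Plant height carries an intrinsic positive bias for flat-topped geometry:
  the region above the trunk cap inside the visual-hull cone
  (height ≈ r_trunk · tan(ring elevation) ≈ 1.5 cm for the default rig) is
  seen by every camera either against the cap itself or within a pixel of
  the silhouette, so no photometric evidence marks it empty, and the
  reconstruction tends to fill it. On the synthetic plant the measured
  height overshoots by about 2 cm (≈ 2.5%): roughly the hull cone plus a
  few millimeters of reconstruction blur. Plants that taper to a tip do not
  have this bias.
* Plant height is measured on the raw isosurface; a single floater inside
  the cylinder above the plant would inflate it. The cylinder mask and the
  high default iso-level make this rare on the synthetic scenes, but real
  captures may need floater filtering (e.g. largest-component selection),
  which is deliberately not applied.
* The azimuth gauge is unfixed; anything compared across runs must be
  azimuth-invariant.
* The exposure model is a single gain per image; it cannot represent
  vignetting or spatially varying illumination within a frame.
* Leaf-level phenotypes (length/width) are out of scope; the mesh is the
  hand-off point.
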