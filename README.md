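# plantnerf

Metric 3D reconstruction and phenotyping of individual plants from orbital
multi-view capture, built around an ROI-focused neural radiance field.

## The problem

High-throughput plant phenotyping needs full 3D models of individual plants,
but photogrammetry pipelines are slow, need background masks, and produce
models in an arbitrary coordinate frame that must be re-scaled by hand. This
package implements a complete pipeline for a "camera-to-plant" orbital rig:
two cameras circle the plant on rings of known radius and heights, and those
rig measurements — not calibration targets — pin the reconstruction to metric
world coordinates. It is aimed at phenotyping researchers who want plant
height (and, from the mesh, other traits) straight from a short orbital
capture.

The stages, each usable as a library module or CLI subcommand:

1. **Keyframe extraction** (`plantnerf.keyframes`). From each view's video,
   equidistant downsampling to 50 frames, rejection of frames whose
   Laplacian-variance sharpness `Var(L) = (1/N) Σ (L_i − μ)²` falls below
   20% of the mean (more than 10 rejections ⇒ the capture itself is
   rejected), then a seeded random subselection of 45 per view — 90 frames.
2. **Pose calibration** (`plantnerf.pose_calib`). SfM poses live in an
   arbitrary similarity frame. A total-least-squares plane fit through the
   camera centers gives the trajectory normal; a Rodrigues rotation `R_vtr`
   maps it to the world z-axis; a Kåsa circle fit gives the virtual ring
   radius and hence the scale `k = r_real / r_virtual`; splitting the rings
   by height and recentering puts the plant at the origin. The plant's
   region of interest is then the box
   `[−r_real, r_real]² × [z_low − h1, z_up + h2]`.
3. **Radiance field** (`plantnerf.field_model`, `plantnerf.render_train`).
   A multi-resolution hash encoding (16 levels, 2-dim features, resolutions
   16 → 2048) feeds a one-hidden-layer density MLP; its 16-dim geometric
   feature plus a frequency-encoded view direction feed a two-hidden-layer
   color MLP. Rays are intersected with the ROI box (slab test); coarse
   samples are placed densely inside `(0, t_max]` and sparsely beyond; the
   coarse field's weights `ω_i = T_i (1 − e^{−σ_i δ_i})` define a
   piecewise-constant PDF that is inverse-transform-sampled for the fine
   pass. Per-image exposure rates `S_i = 2^{E_i}` and SE(3) pose offsets are
   trained jointly with the field by backpropagation (hand-written, numpy).
4. **Mesh + phenotypes** (`plantnerf.mesh_extract`, `plantnerf.evaluate`).
   Densities are sampled on a grid over the ROI's inscribed cylinder and
   polygonized with Marching Cubes at a density threshold; vertices are in
   meters, so plant height is `max z − min z`. Image quality is PSNR
   `10 log10(MAX²/MSE)`; phenotype accuracy is MAE and R².

Everything is testable without any captured data: `plantnerf.scene_sim`
builds an analytic plant (trunk cylinder + ellipsoidal leaves, exactly known
height), orbits synthetic cameras around it, and renders ground-truth images
by dense quadrature of the volume-rendering integral — an oracle independent
of the trained model's renderer.

## Worked example

```python
import numpy as np
from plantnerf import scene_sim, render_train, evaluate
from plantnerf.field_model import FieldConfig, HashGridConfig
from plantnerf.pose_calib import calibrate_poses, compute_roi_aabb, \
    transform_poses_similarity
from plantnerf.mesh_extract import MeshConfig, extract_mesh, mesh_height
from scipy.spatial.transform import Rotation

# synthetic capture: 40 views on two rings (r = 0.75 m), one held-out view
cap = scene_sim.make_capture(seed=0, n_per_ring=20, h=64, w=64,
                             n_quad=128, n_heldout=1)

# emulate SfM's arbitrary frame, then calibrate it back to metric
rng = np.random.default_rng(7)
poses = transform_poses_similarity(
    list(cap.true_poses) + list(cap.heldout_poses),
    Rotation.random(random_state=rng).as_matrix(),
    float(rng.uniform(0.5, 3.0)), rng.uniform(-1, 1, 3))
calibrated, cal = calibrate_poses(poses, cap.prior)
aabb = compute_roi_aabb(cal, cap.prior)

cfg = render_train.TrainConfig(
    n_iters=2000, batch_rays=384, n_coarse=24, n_fine=40,
    field=FieldConfig(
        fine_grid=HashGridConfig(n_levels=16, log2_table_size=15, finest=2048),
        coarse_grid=HashGridConfig(n_levels=8, log2_table_size=13, finest=512),
        density_hidden=32, color_hidden=32, coarse_hidden=16))
field, history = render_train.train(cap.images, calibrated[:-1],
                                    cap.intrinsics, aabb, cfg, seed=0)

img = render_train.render_view(field, calibrated[-1], cap.intrinsics, 64, 64, cfg)
print(f"held-out PSNR: {evaluate.psnr(cap.heldout_frames[0].pixels, img):.2f} dB")

mesh = extract_mesh(field, aabb, MeshConfig(grid_resolution=128))
print(f"plant height: {mesh_height(mesh):.3f} m (true {cap.field.bound_height:.3f} m)")
```

On one CPU core this trains in about six minutes and prints

```
held-out PSNR: 33.86 dB
plant height: 0.820 m (true 0.800 m)
```

— the held-out view is reconstructed at ~34 dB and the plant height comes
out metric, within 2 cm of the analytic plant's exact height (the residual
is dominated by the visual-hull ambiguity above the trunk's flat top; see
`docs/methods.md`).

The same flow runs from the shell:

```bash
plantnerf simulate --out runs/demo/capture --seed 0 --n-per-ring 20 --size 64
plantnerf run-all --config configs/demo.yaml
```

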