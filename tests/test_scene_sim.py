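"""Synthetic scenes and the quadrature reference renderer."""

import numpy as np
import pytest

from plantnerf import keyframes as kf
from plantnerf import scene_sim
from plantnerf.geometry import Pose
from plantnerf.pose_calib import TrajectoryPrior, calibrate_poses
from plantnerf.scene_sim import (
    AnalyticField,
    DEFAULT_PRIOR,
    degrade,
    make_capture,
    make_plant_field,
    make_trajectory,
    make_video_frames,
    render_ground_truth,
)


def _slab_field(sigma, z0, z1, color=(0.2, 0.5, 0.7)):
    """Constant-density horizontal slab inside a wide cylinder."""
    color = np.asarray(color)

    def density(p):
        p = np.atleast_2d(p)
        inside = (p[:, 2] >= z0) & (p[:, 2] <= z1) & (np.hypot(p[:, 0], p[:, 1]) <= 5.0)
        return np.where(inside, sigma, 0.0)

    def colors(p, d):
        return np.tile(color, (len(np.atleast_2d(p)), 1))

    return AnalyticField(density, colors, z1 - z0, 5.0, z0, z1)


class TestPlantField:
    def test_trunk_axis_is_solid(self):
        f = make_plant_field(seed=0, n_leaves=5)
        assert f.density_fn(np.array([[0.0, 0.0, 0.4]]))[0] == 100.0

    def test_far_point_is_empty(self):
        f = make_plant_field(seed=0, n_leaves=5)
        assert f.density_fn(np.array([[10.0, 0.0, 0.4]]))[0] == 0.0

    def test_outside_declared_cylinder_is_empty(self):
        f = make_plant_field(seed=2, n_leaves=10)
        rng = np.random.default_rng(0)
        th = rng.uniform(0, 2 * np.pi, 200)
        r = f.cyl_radius * rng.uniform(1.0, 3.0, 200)
        z = rng.uniform(-1, 2, 200)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th), z])
        assert (f.density_fn(pts) == 0).all()

    def test_deterministic_in_seed(self):
        a = make_plant_field(seed=7, n_leaves=8)
        b = make_plant_field(seed=7, n_leaves=8)
        pts = np.random.default_rng(1).uniform(-0.3, 0.9, (100, 3))
        assert np.array_equal(a.density_fn(pts), b.density_fn(pts))
        d = np.tile([0, 0, 1.0], (100, 1))
        assert np.array_equal(a.color_fn(pts, d), b.color_fn(pts, d))

    def test_bound_height_matches_geometry(self):
        f = make_plant_field(seed=3, n_leaves=12)
        assert f.bound_height == 0.80
        # nothing above the apex or below the ground
        pts_hi = np.random.default_rng(2).uniform(-0.3, 0.3, (300, 3))
        pts_hi[:, 2] = np.random.default_rng(3).uniform(0.801, 1.2, 300)
        assert (f.density_fn(pts_hi) == 0).all()


class TestTrajectory:
    def test_centers_on_exact_circles(self):
        poses = make_trajectory(DEFAULT_PRIOR, 36)
        C = np.stack([p.center for p in poses])
        assert np.allclose(C[:, 0] ** 2 + C[:, 1] ** 2, DEFAULT_PRIOR.r_real**2)

    def test_ring_heights_constant(self):
        poses = make_trajectory(DEFAULT_PRIOR, 36)
        C = np.stack([p.center for p in poses])
        assert set(np.round(C[:, 2], 12)) == {
            DEFAULT_PRIOR.h1,
            DEFAULT_PRIOR.h1 + scene_sim.DEFAULT_RING_GAP,
        }

    def test_count(self):
        assert len(make_trajectory(DEFAULT_PRIOR, 36)) == 72

    def test_optical_axes_hit_the_plant_axis(self):
        for pose in make_trajectory(DEFAULT_PRIOR, 5):
            c2w = pose.as_c2w()
            z_c = c2w.rotation[:, 2]  # optical axis in world coordinates
            o = c2w.translation
            # distance from the line o + t z_c to the vertical axis x = y = 0
            t = -(o[0] * z_c[0] + o[1] * z_c[1]) / (z_c[0] ** 2 + z_c[1] ** 2)
            p = o + t * z_c
            assert np.hypot(p[0], p[1]) < 1e-12

    def test_fixed_point_of_calibration(self):
        poses = make_trajectory(DEFAULT_PRIOR, 8)
        _, cal = calibrate_poses(poses, DEFAULT_PRIOR)
        assert cal.k == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(cal.R_vtr, np.eye(3), atol=1e-9)


class TestReferenceRenderer:
    def _head_on_pose(self, z):
        # camera on the axis below, looking straight up through the slab
        return Pose(np.eye(3), np.array([0.0, 0.0, z]), "c2w")

    def test_empty_field_renders_background(self):
        f = _slab_field(0.0, 0.2, 0.4)
        pose = make_trajectory(DEFAULT_PRIOR, 4)[0]
        intr = scene_sim.default_intrinsics(16, 16)
        img = render_ground_truth(f, pose, intr, 16, 16, 32, background=np.array([0.1, 0.2, 0.3]))
        assert np.allclose(img, [0.1, 0.2, 0.3], atol=1e-12)

    def test_opaque_wall_returns_wall_color(self):
        f = _slab_field(500.0, 0.2, 0.6, color=(0.8, 0.1, 0.3))
        pose = self._head_on_pose(0.0)
        intr = scene_sim.default_intrinsics(8, 8)
        img = render_ground_truth(f, pose, intr, 8, 8, 256)
        center = img[4, 4]
        assert np.allclose(center, [0.8, 0.1, 0.3], atol=1e-3)

    @pytest.mark.parametrize("sigma_l", [0.0, 0.5, 5.0])
    def test_slab_alpha_converges_to_closed_form(self, sigma_l):
        L = 0.4
        f = _slab_field(sigma_l / L, 0.2, 0.2 + L)
        pose = self._head_on_pose(0.0)
        # odd image size: the central pixel's ray runs exactly up the axis,
        # so its optical depth through the slab is exactly sigma_l
        intr = scene_sim.default_intrinsics(5, 5)
        bg = np.array([1.0, 1.0, 1.0])
        expected = np.array([0.2, 0.5, 0.7]) * (1 - np.exp(-sigma_l)) + bg * np.exp(-sigma_l)
        errs = []
        for n_quad in (64, 512, 4096):
            img = render_ground_truth(f, pose, intr, 5, 5, n_quad, background=bg)
            errs.append(np.abs(img[2, 2] - expected).max())
        # quadrature over the exact slab interval with constant density is
        # exact up to round-off at every n_quad
        assert max(errs) < 1e-8

    def test_cauchy_convergence_in_n_quad(self):
        f = make_plant_field(seed=0, n_leaves=6)
        pose = make_trajectory(DEFAULT_PRIOR, 4)[0]
        intr = scene_sim.default_intrinsics(16, 16)
        imgs = {
            n: render_ground_truth(f, pose, intr, 16, 16, n) for n in (32, 64, 128)
        }
        d_coarse = np.abs(imgs[64] - imgs[32]).max()
        d_fine = np.abs(imgs[128] - imgs[64]).max()
        assert d_fine < d_coarse


class TestDegrade:
    def test_identity(self, tiny_capture):
        out = degrade(tiny_capture)
        for a, b in zip(out.frames, tiny_capture.frames):
            assert np.array_equal(a.pixels, b.pixels)

    def test_exposure_doubles_unsaturated_frame(self, tiny_capture):
        n = len(tiny_capture.frames)
        exps = np.zeros(n)
        exps[0] = 1.0
        out = degrade(tiny_capture, exposure_exps=exps)
        src = tiny_capture.frames[0].pixels
        assert (src * 2 <= 1.0).all()  # palette chosen to stay unsaturated
        assert np.allclose(out.frames[0].pixels, 2 * src)

    def test_blur_lowers_laplacian_variance(self, tiny_capture):
        out = degrade(tiny_capture, blur_ids=[1], blur_sigma=2.0)
        assert out.frames[1].sharpness < tiny_capture.frames[1].sharpness
        assert 1 in out.blurred_ids

    def test_quantize_rounds_to_8bit(self, tiny_capture):
        out = degrade(tiny_capture, quantize=True)
        q = out.frames[0].pixels
        assert np.allclose(q * 255, np.round(q * 255), atol=1e-9)


class TestVideoFrames:
    def test_sharp_and_blurred_scores_separate(self):
        frames = make_video_frames(6, seed=0, blur_ids={"lower": [2]})
        sharp = kf.laplacian_variance(frames["lower"][0])
        blurred = kf.laplacian_variance(frames["lower"][2])
        assert blurred < 0.2 * sharp

    def test_deterministic(self):
        a = make_video_frames(4, seed=9)
        b = make_video_frames(4, seed=9)
        assert all(
            np.array_equal(x, y) for x, y in zip(a["upper"], b["upper"])
        )


def test_capture_structure(tiny_capture):
    cap = tiny_capture
    assert len(cap.frames) == len(cap.true_poses) == 12
    views = {f.view_id for f in cap.frames}
    assert views == {"lower", "upper"}
    assert len(cap.heldout_frames) == 1
    assert cap.images.shape == (12, 32, 32, 3)
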