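"""End-to-end orchestration: frames -> calibrate -> train -> mesh -> evaluate.

Each stage writes its outputs (plus a small JSON manifest) under the run
directory and is skipped on re-runs when those outputs already exist, so a
run is resumable per stage: deleting a stage's outputs re-executes exactly
that stage.
"""

from __future__ import annotations

import csv
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import keyframes as kf
from . import scene_sim, sfm_io
from .config import PipelineConfig
from .evaluate import MetricReport
from .field_model import RadianceField
from .geometry import Pose
from .mesh_extract import extract_mesh, mesh_height, save_mesh
from .pose_calib import (
    calibrate_poses,
    compute_roi_aabb,
    transform_poses_similarity,
)
from .render_train import render_view, train

__all__ = ["run_pipeline"]


def _manifest(path: Path, stage: str, seed: int, t0: float, **extra) -> None:
    payload = {"stage": stage, "seed": seed, "seconds": round(time.time() - t0, 3)}
    payload.update(extra)
    path.write_text(json.dumps(payload, indent=2))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    marker = out / "capture" / "manifest.json"
    if marker.exists():
        return
    t0 = time.time()
    sc = cfg.scene
    capture = scene_sim.make_capture(
        seed=cfg.seed,
        n_per_ring=sc.n_per_ring,
        h=sc.height,
        w=sc.width,
        n_quad=sc.n_quad,
        n_leaves=sc.n_leaves,
        n_heldout=sc.n_heldout,
    )
    cap_dir = out / "capture"
    all_poses = list(capture.true_poses) + list(capture.heldout_poses)
    if sc.perturb_similarity:
        rng = np.random.default_rng(cfg.seed + 101)
        from scipy.spatial.transform import Rotation

        Q = Rotation.random(random_state=rng).as_matrix()
        s = float(rng.uniform(0.5, 3.0))
        u = rng.uniform(-1.0, 1.0, 3)
        all_poses = transform_poses_similarity(all_poses, Q, s, u)
    n_train = len(capture.true_poses)
    virtual = scene_sim.SyntheticCapture(
        frames=capture.frames,
        true_poses=tuple(all_poses[:n_train]),
        intrinsics=capture.intrinsics,
        prior=capture.prior,
        true_exposures=capture.true_exposures,
        blurred_ids=capture.blurred_ids,
        background=capture.background,
    )
    sfm_io.write_capture(virtual, cap_dir)
    # held-out views go into the same model (calibrated but never trained on)
    ho_dir = cap_dir / "heldout"
    ho_dir.mkdir(parents=True, exist_ok=True)
    ho_names = []
    for f, pose in zip(capture.heldout_frames, capture.heldout_poses):
        name = f"heldout_{f.source_index:04d}.png"
        sfm_io.save_image(ho_dir / name, f.pixels)
        ho_names.append(name)
    frame_names = [f"{f.view_id}_{f.source_index:04d}.png" for f in capture.frames]
    sfm_io.write_sfm_model(
        cap_dir / "sparse", capture.intrinsics, all_poses, frame_names + ho_names
    )
    meta = {"bound_height": capture.field.bound_height if capture.field else None}
    _manifest(marker, "simulate", cfg.seed, t0, n_frames=len(capture.frames), **meta)


def _stage_keyframes(cfg: PipelineConfig, out: Path) -> None:
    marker = out / "keyframes.csv"
    if marker.exists():
        return
    t0 = time.time()
    images, names = sfm_io.read_capture_frames(out / "capture")
    by_view: dict[str, list] = {}
    name_of: dict[tuple, str] = {}
    for img, name in zip(images, names):
        view = name.rsplit("_", 1)[0]
        idx = len(by_view.setdefault(view, []))
        name_of[(view, idx)] = name
        by_view[view].append(img)
    k = cfg.keyframes
    try:
        fs = kf.equidistant_downsample(by_view, k.target_per_view)
        fs = kf.eliminate_blurry(fs, k.rel_threshold, k.max_removed)
        fs = kf.select_keyframes(fs, k.per_view, seed=cfg.seed)
    except (ValueError, kf.QualityGateError) as exc:
        raise PipelineError("keyframes", str(exc)) from exc
    with open(marker, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "view", "source_index", "sharpness"])
        for f in fs.frames:
            # source_index refers into the downsampled per-view list ordering
            writer.writerow(
                [
                    name_of[(f.view_id, f.source_index)]
                    if (f.view_id, f.source_index) in name_of
                    else f"{f.view_id}_{f.source_index:04d}.png",
                    f.view_id,
                    f.source_index,
                    f"{f.sharpness:.8g}",
                ]
            )


def _stage_calibrate(cfg: PipelineConfig, out: Path) -> None:
    marker = out / "calibration.yaml"
    if marker.exists():
        return
    t0 = time.time()
    try:
        intr, poses, names = sfm_io.read_sfm_model(out / "capture" / "sparse")
        prior = sfm_io.read_prior(out / "capture" / "prior.yaml")
        calibrated, cal = calibrate_poses(poses, prior)
        aabb = compute_roi_aabb(cal, prior)
    except (ValueError, FileNotFoundError) as exc:
        raise PipelineError("calibrate", str(exc)) from exc
    sfm_io.write_sfm_model(out / "sparse_calibrated", intr, calibrated, names)
    marker.write_text(
        yaml.safe_dump(
            {
                "R_vtr": cal.R_vtr.tolist(),
                "k": cal.k,
                "t_s": cal.t_s.tolist(),
                "z_up": cal.z_up,
                "z_low": cal.z_low,
                "r_virtual": cal.r_virtual,
                "aabb": [aabb.min_corner.tolist(), aabb.max_corner.tolist()],
                "seed": cfg.seed,
            }
        )
    )


def _read_calibrated(out: Path):
    intr, poses, names = sfm_io.read_sfm_model(out / "sparse_calibrated")
    cal = yaml.safe_load((out / "calibration.yaml").read_text())
    from .geometry import Aabb

    aabb = Aabb(np.array(cal["aabb"][0]), np.array(cal["aabb"][1]))
    return intr, poses, names, aabb


def _stage_train(cfg: PipelineConfig, out: Path) -> None:
    marker = out / "checkpoint.npz"
    if marker.exists():
        return
    t0 = time.time()
    intr, poses, names, aabb = _read_calibrated(out)
    selected = []
    with open(out / "keyframes.csv") as fh:
        selected = [row["filename"] for row in csv.DictReader(fh)]
    pose_of = dict(zip(names, poses))
    frames_dir = out / "capture" / "frames"
    images = np.stack([sfm_io.load_image(frames_dir / n) for n in selected])
    train_poses = [pose_of[n] for n in selected]
    log_rows = []
    field, history = train(
        images,
        train_poses,
        intr,
        aabb,
        cfg.train,
        seed=cfg.seed,
        log=lambda it, loss: log_rows.append((it, loss)),
    )
    field.save(marker)
    with open(out / "train_log.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "loss"])
        writer.writerows(history)
    _manifest(out / "train_manifest.json", "train", cfg.seed, t0, n_images=len(images))


def _stage_mesh_and_render(cfg: PipelineConfig, out: Path) -> None:
    mesh_path = out / "mesh.ply"
    render_dir = out / "renders"
    if mesh_path.exists() and render_dir.exists():
        return
    field = RadianceField.load(out / "checkpoint.npz")
    intr, poses, names, aabb = _read_calibrated(out)
    mesh = extract_mesh(field, aabb, cfg.mesh)
    if not mesh.is_empty:
        save_mesh(mesh, mesh_path)
    else:
        mesh_path.write_text("")  # placeholder: empty isosurface
    render_dir.mkdir(exist_ok=True)
    ho = [(n, p) for n, p in zip(names, poses) if n.startswith("heldout")]
    for name, pose in ho:
        img = render_view(field, pose, intr, intr.height, intr.width, cfg.train)
        sfm_io.save_image(render_dir / name, img)


def _stage_evaluate(cfg: PipelineConfig, out: Path) -> None:
    marker = out / "report.json"
    if marker.exists():
        return
    field = RadianceField.load(out / "checkpoint.npz")
    intr, poses, names, aabb = _read_calibrated(out)
    report = MetricReport(max_i=1.0)
    ho_dir = out / "capture" / "heldout"
    for name in sorted(p.name for p in ho_dir.glob("*.png")) if ho_dir.exists() else []:
        gt = sfm_io.load_image(ho_dir / name)
        pred = sfm_io.load_image(out / "renders" / name)
        report.add(gt, pred)
    result = {"image_quality": report.to_dict()}
    mesh_file = out / "mesh.ply"
    if mesh_file.exists() and mesh_file.stat().st_size > 0:
        import trimesh

        tm = trimesh.load(mesh_file, process=False)
        z = np.asarray(tm.vertices)[:, 2]
        result["plant_height_m"] = float(z.max() - z.min())
    sim = out / "capture" / "manifest.json"
    if sim.exists():
        meta = json.loads(sim.read_text())
        if meta.get("bound_height"):
            result["true_height_m"] = meta["bound_height"]
    marker.write_text(json.dumps(result, indent=2))


_STAGES = [
    ("simulate", _stage_simulate),
    ("keyframes", _stage_keyframes),
    ("calibrate", _stage_calibrate),
    ("train", _stage_train),
    ("mesh", _stage_mesh_and_render),
    ("evaluate", _stage_evaluate),
]


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages under ``cfg.out_dir``; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, fn in _STAGES:
        if name == "simulate" and not cfg.simulate:
            continue
        try:
            fn(cfg, out)
        except PipelineError:
            raise
        except Exception as exc:  # halt with a stage-tagged message
            raise PipelineError(name, str(exc)) from exc
    return out
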