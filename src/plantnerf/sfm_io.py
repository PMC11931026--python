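"""Format adapters: COLMAP-style text models, PNG frames, trajectory priors.

Poses in ``images.txt`` follow the SfM convention (world-to-camera rotation
as a quaternion ``QW QX QY QZ`` plus translation; the camera center is
``-R.T t``). Camera models PINHOLE, OPENCV and FULL_OPENCV are supported on
read; synthetic captures are written as PINHOLE.

Images are undistorted once at ingest (inverse-mapping resampling of the
Brown-Conrady model), so every downstream module assumes an ideal pinhole.
"""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .geometry import Intrinsics, Pose
from .pose_calib import TrajectoryPrior

__all__ = [
    "read_sfm_model",
    "write_sfm_model",
    "read_prior",
    "write_prior",
    "load_image",
    "save_image",
    "undistort_image",
    "write_capture",
    "read_capture_frames",
]


def _parse_camera_line(parts: list[str]) -> Intrinsics:
    model = parts[1]
    width, height = int(parts[2]), int(parts[3])
    params = [float(p) for p in parts[4:]]
    if model == "PINHOLE":
        fx, fy, cx, cy = params
        return Intrinsics(fx, fy, cx, cy, width, height)
    if model == "OPENCV":
        fx, fy, cx, cy, k1, k2, p1, p2 = params
        return Intrinsics(fx, fy, cx, cy, width, height, k1=k1, k2=k2, p1=p1, p2=p2)
    if model == "FULL_OPENCV":
        fx, fy, cx, cy, k1, k2, p1, p2, k3 = params[:9]
        return Intrinsics(fx, fy, cx, cy, width, height, k1=k1, k2=k2, k3=k3, p1=p1, p2=p2)
    raise ValueError(f"unsupported camera model {model!r}")


def read_sfm_model(model_dir) -> tuple[Intrinsics, list[Pose], list[str]]:
    """Parse a COLMAP text model: (intrinsics, w2c poses, image names).

    Poses are sorted by image name so they align with sorted frame files.
    """
    model_dir = Path(model_dir)
    cam_file = model_dir / "cameras.txt"
    img_file = model_dir / "images.txt"
    if not cam_file.exists():
        raise FileNotFoundError(f"missing {cam_file}")
    if not img_file.exists():
        raise FileNotFoundError(f"missing {img_file}")

    intr = None
    for line in cam_file.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        intr = _parse_camera_line(line.split())
        break
    if intr is None:
        raise ValueError("cameras.txt contains no camera")

    entries = []
    lines = [
        l for l in img_file.read_text().splitlines() if not l.strip().startswith("#")
    ]
    # images.txt alternates pose lines and (possibly empty) 2D-point lines;
    # keep blank lines so the alternation survives empty point lists
    for line in lines[::2]:
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 10:
            raise ValueError(f"malformed images.txt line: {line!r}")
        qw, qx, qy, qz = map(float, parts[1:5])
        t = np.array(list(map(float, parts[5:8])))
        R = Rotation.from_quat([qx, qy, qz, qw]).as_matrix()
        entries.append((parts[9], Pose(R, t, "w2c")))
    entries.sort(key=lambda e: e[0])
    names = [e[0] for e in entries]
    poses = [e[1] for e in entries]
    return intr, poses, names


def write_sfm_model(model_dir, intr: Intrinsics, poses, names) -> None:
    """Write a COLMAP-style text model (PINHOLE camera, empty points3D)."""
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    with open(model_dir / "cameras.txt", "w") as fh:
        fh.write("# Camera list: CAMERA_ID MODEL WIDTH HEIGHT PARAMS[]\n")
        fh.write(
            f"1 PINHOLE {intr.width} {intr.height} "
            f"{intr.fx:.12g} {intr.fy:.12g} {intr.cx:.12g} {intr.cy:.12g}\n"
        )
    with open(model_dir / "images.txt", "w") as fh:
        fh.write("# Image list: IMAGE_ID QW QX QY QZ TX TY TZ CAMERA_ID NAME\n")
        for i, (pose, name) in enumerate(zip(poses, names), start=1):
            w2c = pose.as_w2c()
            qx, qy, qz, qw = Rotation.from_matrix(w2c.rotation).as_quat()
            t = w2c.translation
            fh.write(
                f"{i} {qw:.12g} {qx:.12g} {qy:.12g} {qz:.12g} "
                f"{t[0]:.12g} {t[1]:.12g} {t[2]:.12g} 1 {name}\n\n"
            )
    (model_dir / "points3D.txt").write_text("# empty\n")


def read_prior(path) -> TrajectoryPrior:
    data = yaml.safe_load(Path(path).read_text())
    return TrajectoryPrior(
        r_real=float(data["r_real"]), h1=float(data["h1"]), h2=float(data["h2"])
    )


def write_prior(path, prior: TrajectoryPrior) -> None:
    Path(path).write_text(
        yaml.safe_dump({"r_real": prior.r_real, "h1": prior.h1, "h2": prior.h2})
    )


def load_image(path) -> np.ndarray:
    """PNG/JPEG -> float RGB in [0, 1]."""
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return img[..., :3].astype(float) / 255.0


def save_image(path, img: np.ndarray) -> None:
    iio.imwrite(path, (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8))


def undistort_image(image: np.ndarray, intr: Intrinsics) -> np.ndarray:
    """Resample a distorted image onto the ideal pinhole grid.

    For every ideal pixel, the Brown-Conrady model (k1, k2, k3 radial; p1, p2
    tangential) gives the source location in the distorted image, which is
    sampled bilinearly. A distortion-free camera returns the input unchanged.
    """
    if not intr.has_distortion:
        return np.asarray(image, dtype=float)
    h, w = image.shape[:2]
    vv, uu = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    y = (vv + 0.5 - intr.cy) / intr.fy
    x = (uu + 0.5 - intr.cx - intr.skew * y) / intr.fx
    r2 = x * x + y * y
    radial = 1.0 + intr.k1 * r2 + intr.k2 * r2**2 + intr.k3 * r2**3
    x_d = x * radial + 2 * intr.p1 * x * y + intr.p2 * (r2 + 2 * x * x)
    y_d = y * radial + intr.p1 * (r2 + 2 * y * y) + 2 * intr.p2 * x * y
    src_u = intr.fx * x_d + intr.skew * y_d + intr.cx - 0.5
    src_v = intr.fy * y_d + intr.cy - 0.5
    out = np.empty_like(np.asarray(image, dtype=float))
    for c in range(image.shape[2]):
        out[..., c] = ndimage.map_coordinates(
            image[..., c], [src_v, src_u], order=1, mode="nearest"
        )
    return out


def write_capture(capture, out_dir) -> None:
    """Materialize a synthetic capture: PNGs, COLMAP model, prior, manifest."""
    out_dir = Path(out_dir)
    frames_dir = out_dir / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    names = []
    with open(out_dir / "frames.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "view", "source_index", "sharpness"])
        for f in capture.frames:
            name = f"{f.view_id}_{f.source_index:04d}.png"
            save_image(frames_dir / name, f.pixels)
            writer.writerow([name, f.view_id, f.source_index, f"{f.sharpness:.8g}"])
            names.append(name)
    write_sfm_model(out_dir / "sparse", capture.intrinsics, capture.true_poses, names)
    write_prior(out_dir / "prior.yaml", capture.prior)


def read_capture_frames(out_dir) -> tuple[list[np.ndarray], list[str]]:
    """Load the PNG frames of a materialized capture, sorted by name."""
    frames_dir = Path(out_dir) / "frames"
    names = sorted(p.name for p in frames_dir.glob("*.png"))
    return [load_image(frames_dir / n) for n in names], names
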