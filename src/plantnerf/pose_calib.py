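"""Global similarity calibration of SfM poses from the orbital-trajectory prior.

SfM recovers camera poses only up to an arbitrary rotation, uniform scale and
translation ("virtual coordinates"). The acquisition rig, however, moves the
two cameras on horizontal circles of known radius ``r_real`` at known heights,
which pins the similarity down (up to an azimuthal rotation about the plant
axis, which the circular prior cannot fix and which is irrelevant for an
axially centered plant):

1. total-least-squares plane fit through all camera centers; the plane normal
   is the world z-axis,
2. a Rodrigues rotation ``R_vtr`` mapping that normal onto (0, 0, 1),
3. an algebraic (Kasa) circle fit of the rotated centers projected to XY,
   giving the virtual radius; the scale is ``k = r_real / r_virtual``,
4. a ring split by height gives mean ring heights ``z_up, z_low``; the
   translation ``t_s = (x_c, y_c, (z_up + z_low)/2)`` recenters the plant at
   the origin.

Calibrated centers then lie on two circles of radius ``r_real`` centered on
the z-axis and vertically centered at 0, and the ROI bounding box of the
plant follows directly from the prior heights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import Aabb, Intrinsics, Pose, skew

__all__ = [
    "Intrinsics",
    "Pose",
    "Aabb",
    "TrajectoryPrior",
    "SimilarityCalibration",
    "fit_plane",
    "rotation_from_normal",
    "fit_circle_2d",
    "split_rings",
    "calibrate_poses",
    "compute_roi_aabb",
    "transform_poses_similarity",
]


@dataclass(frozen=True)
class TrajectoryPrior:
    """Rig geometry recorded at capture time (all in meters).

    ``r_real``: radius of the camera rings; ``h1``: height of the lower camera
    above the ground; ``h2``: distance from the upper camera to the top of the
    camera bracket.
    """

    r_real: float
    h1: float
    h2: float

    def __post_init__(self) -> None:
        if min(self.r_real, self.h1, self.h2) <= 0:
            raise ValueError("trajectory prior entries must be positive")


@dataclass(frozen=True)
class SimilarityCalibration:
    """Recovered virtual-to-real similarity plus derived ring geometry.

    ``z_up``/``z_low`` are the mean ring heights *after* recentering, i.e.
    symmetric about 0.
    """

    R_vtr: np.ndarray
    k: float
    t_s: np.ndarray
    z_up: float
    z_low: float
    r_virtual: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("scale factor must be positive")
        if not self.z_up > self.z_low:
            raise ValueError("z_up must exceed z_low")


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Total-least-squares plane through 3D points.

    Returns ``(normal, offset)`` with ``normal . x = offset`` for points on
    the plane; the normal sign is chosen with a non-negative z-component.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("points are collinear; plane fit is degenerate")
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal
    return normal, float(normal @ centroid)


def rotation_from_normal(n: np.ndarray) -> np.ndarray:
    """Rodrigues rotation mapping the unit normal ``n`` onto (0, 0, 1).

    Axis is ``n x e_z``, angle ``arccos(n . e_z)``. The antiparallel case
    (n ~ -e_z) rotates by pi about the x-axis.
    """
    n = np.asarray(n, dtype=float).reshape(3)
    if abs(np.linalg.norm(n) - 1.0) > 1e-8:
        raise ValueError("normal must be a unit vector")
    e_z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(n, e_z)
    s = np.linalg.norm(axis)
    c = float(n @ e_z)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        return np.diag([1.0, -1.0, -1.0])  # pi about x
    K = skew(axis / s)
    theta = np.arctan2(s, c)
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def fit_circle_2d(points: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle fit; returns (x_c, y_c, radius)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 2")
    x, y = pts[:, 0], pts[:, 1]
    A = np.stack([2 * x, 2 * y, np.ones_like(x)], axis=1)
    b = x * x + y * y
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("points are collinear; circle fit is degenerate")
    xc, yc, c = sol
    r2 = c + xc * xc + yc * yc
    if r2 <= 0:
        raise ValueError("degenerate circle fit (non-positive radius)")
    return float(xc), float(yc), float(np.sqrt(r2))


def split_rings(positions: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Split orientation-calibrated camera centers into upper/lower rings.

    Splits at the midpoint of the z-range; returns (upper_idx, lower_idx,
    z_up, z_low) with the ring heights as mean z of each group.
    """
    pts = np.asarray(positions, dtype=float)
    z = pts[:, 2]
    z_span = z.max() - z.min()
    if z_span < 1e-9 * max(1.0, abs(z).max()):
        raise ValueError("all centers at one height: cannot split a single ring")
    mid = 0.5 * (z.max() + z.min())
    upper = np.flatnonzero(z >= mid)
    lower = np.flatnonzero(z < mid)
    if len(upper) == 0 or len(lower) == 0:  # pragma: no cover - mid splits by construction
        raise ValueError("ring split produced an empty group")
    return upper, lower, float(z[upper].mean()), float(z[lower].mean())


def calibrate_poses(
    poses: Sequence[Pose], prior: TrajectoryPrior
) -> tuple[list[Pose], SimilarityCalibration]:
    """Map SfM poses to metric world coordinates using the trajectory prior.

    Applies, in order, the orientation calibration ``R_vtr`` (plane normal to
    z-axis), the scale ``k = r_real / r_virtual`` from the circle fit, and the
    recentering translation ``t_s``. Output poses are returned in each input
    pose's own convention.
    """
    if len(poses) < 6:
        raise ValueError("need at least 6 poses spanning two rings")
    centers = np.stack([p.center for p in poses])

    normal, _ = fit_plane(centers)
    R_vtr = rotation_from_normal(normal)
    rotated = centers @ R_vtr.T

    xc_v, yc_v, r_virtual = fit_circle_2d(rotated[:, :2])
    k = prior.r_real / r_virtual
    scaled = k * rotated

    _, _, z_up_raw, z_low_raw = split_rings(scaled)
    z_c = 0.5 * (z_up_raw + z_low_raw)
    # the circle center was fitted before scaling; bring it to the same scale
    t_s = np.array([k * xc_v, k * yc_v, z_c])

    calibrated = []
    for p in poses:
        c2w = p.as_c2w()
        R_new = R_vtr @ c2w.rotation
        center_new = k * (R_vtr @ c2w.translation) - t_s
        calibrated.append(Pose(R_new, center_new, "c2w").as_convention(p.convention))

    cal = SimilarityCalibration(
        R_vtr=R_vtr,
        k=float(k),
        t_s=t_s,
        z_up=float(z_up_raw - z_c),
        z_low=float(z_low_raw - z_c),
        r_virtual=float(r_virtual),
    )
    return calibrated, cal


def compute_roi_aabb(cal: SimilarityCalibration, prior: TrajectoryPrior) -> Aabb:
    """ROI bounding box of the plant from calibrated ring heights and the prior.

    min = (-r_real, -r_real, z_low - h1), max = (r_real, r_real, z_up + h2):
    horizontally the rings enclose the plant, vertically the box spans from the
    ground (lower camera minus its height above ground) to the bracket top.
    """
    lo = np.array([-prior.r_real, -prior.r_real, cal.z_low - prior.h1])
    hi = np.array([prior.r_real, prior.r_real, cal.z_up + prior.h2])
    if lo[2] >= hi[2]:
        raise ValueError("inconsistent prior: ROI has non-positive height")
    return Aabb(lo, hi)


def transform_poses_similarity(
    poses: Sequence[Pose], rotation: np.ndarray, scale: float, translation: np.ndarray
) -> list[Pose]:
    """Re-express poses after the similarity world map x -> scale * R x + u.

    Used to emulate SfM's arbitrary coordinate frame from ground-truth poses.
    """
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float).reshape(3)
    if scale <= 0:
        raise ValueError("scale must be positive")
    out = []
    for p in poses:
        c2w = p.as_c2w()
        R_new = rotation @ c2w.rotation
        c_new = scale * (rotation @ c2w.translation) + translation
        out.append(Pose(R_new, c_new, "c2w").as_convention(p.convention))
    return out
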