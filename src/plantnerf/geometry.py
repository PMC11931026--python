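"""Shared camera and geometry primitives.

Conventions used throughout the package:

* World frame: z-up, metric meters, origin at the plant center after pose
  calibration.
* Camera frame: OpenCV/COLMAP convention — +x right, +y down, +z through the
  lens (optical axis).
* A :class:`Pose` stores a rotation and translation plus a ``convention`` flag:
  ``"w2c"`` (world-to-camera, the SfM text-model convention, where the camera
  center is ``-R.T @ t``) or ``"c2w"`` (camera-to-world, where the translation
  *is* the camera center).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Intrinsics",
    "Pose",
    "Aabb",
    "look_at_pose",
    "camera_ray_directions",
    "so3_exp",
    "so3_log",
    "so3_right_jacobian",
    "skew",
]

_ORTHO_ATOL = 1e-7


@dataclass(frozen=True)
class Intrinsics:
    """Pinhole intrinsics with a Brown–Conrady distortion model.

    ``fx, fy, cx, cy, skew`` are in pixels; the distortion coefficients
    ``k1, k2, k3`` (radial) and ``p1, p2`` (tangential) are dimensionless.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    skew: float = 0.0
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")

    @property
    def has_distortion(self) -> bool:
        return any(abs(c) > 0 for c in (self.k1, self.k2, self.k3, self.p1, self.p2))

    def matrix(self) -> np.ndarray:
        """3x3 calibration matrix A."""
        return np.array(
            [
                [self.fx, self.skew, self.cx],
                [0.0, self.fy, self.cy],
                [0.0, 0.0, 1.0],
            ]
        )


def _check_rotation(R: np.ndarray) -> None:
    if R.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_ATOL):
        raise ValueError("rotation is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("rotation has negative determinant (reflection)")


@dataclass(frozen=True)
class Pose:
    """Rigid camera pose with an explicit storage convention."""

    rotation: np.ndarray
    translation: np.ndarray
    convention: str = "w2c"

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        _check_rotation(R)
        if self.convention not in ("w2c", "c2w"):
            raise ValueError(f"unknown pose convention {self.convention!r}")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates."""
        if self.convention == "c2w":
            return self.translation
        return -self.rotation.T @ self.translation

    @property
    def R_c2w(self) -> np.ndarray:
        return self.rotation if self.convention == "c2w" else self.rotation.T

    def as_c2w(self) -> "Pose":
        if self.convention == "c2w":
            return self
        return Pose(self.rotation.T, self.center, "c2w")

    def as_w2c(self) -> "Pose":
        if self.convention == "w2c":
            return self
        R = self.rotation.T
        return Pose(R, -R @ self.translation, "w2c")

    def as_convention(self, convention: str) -> "Pose":
        return self.as_c2w() if convention == "c2w" else self.as_w2c()


@dataclass(frozen=True)
class Aabb:
    """Axis-aligned bounding box in metric world coordinates."""

    min_corner: np.ndarray
    max_corner: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.min_corner, dtype=float).reshape(3)
        hi = np.asarray(self.max_corner, dtype=float).reshape(3)
        if not np.all(lo < hi):
            raise ValueError("AABB min_corner must be strictly below max_corner")
        object.__setattr__(self, "min_corner", lo)
        object.__setattr__(self, "max_corner", hi)

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.min_corner + self.max_corner)

    @property
    def size(self) -> np.ndarray:
        return self.max_corner - self.min_corner

    @property
    def diagonal(self) -> float:
        return float(np.linalg.norm(self.size))

    def contains(self, points: np.ndarray, atol: float = 0.0) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.all((p >= self.min_corner - atol) & (p <= self.max_corner + atol), axis=-1)

    def dilated(self, margin: float) -> "Aabb":
        return Aabb(self.min_corner - margin, self.max_corner + margin)


def look_at_pose(position, target, up=(0.0, 0.0, 1.0)) -> Pose:
    """Camera-to-world pose at ``position`` with the optical axis through ``target``."""
    position = np.asarray(position, dtype=float)
    forward = np.asarray(target, dtype=float) - position
    n = np.linalg.norm(forward)
    if n == 0:
        raise ValueError("look-at target coincides with camera position")
    z_c = forward / n
    x_c = np.cross(z_c, np.asarray(up, dtype=float))
    nx = np.linalg.norm(x_c)
    if nx < 1e-12:
        # optical axis parallel to up: pick an arbitrary horizontal right vector
        x_c = np.array([1.0, 0.0, 0.0])
    else:
        x_c = x_c / nx
    y_c = np.cross(z_c, x_c)
    R_c2w = np.stack([x_c, y_c, z_c], axis=1)
    return Pose(R_c2w, position, "c2w")


def camera_ray_directions(intr: Intrinsics, h: int, w: int, pixels=None) -> np.ndarray:
    """Unit ray directions in the *camera* frame for pixel centers.

    ``pixels`` is an optional (N, 2) array of (row, col) indices; by default a
    full h x w grid is returned in row-major order, shape (h*w, 3).
    Distortion is not applied here — images are undistorted at ingest.
    """
    if pixels is None:
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        pixels = np.stack([rr.ravel(), cc.ravel()], axis=1)
    pixels = np.asarray(pixels, dtype=float)
    u = pixels[:, 1] + 0.5
    v = pixels[:, 0] + 0.5
    y = (v - intr.cy) / intr.fy
    x = (u - intr.cx - intr.skew * y) / intr.fx
    d = np.stack([x, y, np.ones_like(x)], axis=1)
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def skew(v: np.ndarray) -> np.ndarray:
    """Cross-product matrix [v]x such that skew(v) @ w == cross(v, w)."""
    v = np.asarray(v, dtype=float).reshape(3)
    return np.array(
        [
            [0.0, -v[2], v[1]],
            [v[2], 0.0, -v[0]],
            [-v[1], v[0], 0.0],
        ]
    )


def so3_exp(rotvec: np.ndarray) -> np.ndarray:
    """Rodrigues exponential map: axis-angle vector -> rotation matrix."""
    return Rotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix()


def so3_log(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`so3_exp` (principal branch, |theta| <= pi)."""
    return Rotation.from_matrix(np.asarray(R, dtype=float)).as_rotvec()


def so3_right_jacobian(rotvec: np.ndarray) -> np.ndarray:
    """Right Jacobian J_r of SO(3): exp((v + dv)^) ~= exp(v^) exp((J_r dv)^)."""
    v = np.asarray(rotvec, dtype=float).reshape(3)
    theta = np.linalg.norm(v)
    K = skew(v)
    if theta < 1e-8:
        return np.eye(3) - 0.5 * K + K @ K / 6.0
    t2 = theta * theta
    return (
        np.eye(3)
        - (1.0 - np.cos(theta)) / t2 * K
        + (theta - np.sin(theta)) / (t2 * theta) * (K @ K)
    )
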