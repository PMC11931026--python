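"""Metric mesh extraction from the trained density field.

The ROI box is discretized on a regular grid, densities queried from the
field, voxels outside the inscribed cylinder of the box zeroed (the plant
stands on the rig axis; the cylinder trims box-corner clutter the cameras
never constrain), and the isosurface at a density threshold polygonized with
Marching Cubes. Vertices come out in metric world coordinates, so phenotype
measurements (plant height = z-extent) read off the mesh directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import marching_cubes

from .geometry import Aabb
from .field_model import RadianceField

__all__ = ["MeshConfig", "Mesh", "sample_density_grid", "extract_mesh", "mesh_height", "save_mesh"]


@dataclass(frozen=True)
class MeshConfig:
    """Grid resolution (voxels per axis), iso threshold, and cylinder trim."""

    grid_resolution: int = 256
    # iso level halfway between empty space and fully solid matter at the
    # scene's density scale (the occupancy-field 0.5-level analogue)
    sigma_threshold: float = 50.0
    cylinder_mask: bool = True
    with_colors: bool = False

    def __post_init__(self) -> None:
        if self.grid_resolution < 8:
            raise ValueError("grid_resolution must be at least 8")
        if self.sigma_threshold <= 0:
            raise ValueError("sigma_threshold must be positive")


@dataclass(frozen=True)
class Mesh:
    vertices: np.ndarray  # (n, 3) meters
    faces: np.ndarray  # (m, 3) vertex indices
    vertex_colors: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        f = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if np.any(~np.isfinite(v)):
            raise ValueError("mesh has non-finite vertices")
        if len(f) and (f.min() < 0 or f.max() >= max(len(v), 1)):
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def is_empty(self) -> bool:
        return len(self.vertices) == 0


def sample_density_grid(
    field_or_fn, aabb: Aabb, res: int, cylinder_mask: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Densities on a regular res^3 grid over the box, cylinder-masked.

    ``field_or_fn`` is a :class:`RadianceField` or any callable mapping
    (N, 3) world points to densities. Grid corner coordinates coincide with
    the box corners. Returns ``(densities, mask)`` where masked-out points
    (outside the inscribed cylinder, radius = half the box's x-extent) are
    zeroed.
    """
    axes = [np.linspace(aabb.min_corner[a], aabb.max_corner[a], res) for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    if isinstance(field_or_fn, RadianceField):
        dens = field_or_fn.query_density(pts)
    else:
        dens = np.asarray(field_or_fn(pts), dtype=float)
    dens = dens.reshape(res, res, res)
    cx, cy = aabb.center[0], aabb.center[1]
    r = 0.5 * aabb.size[0]
    mask = (X - cx) ** 2 + (Y - cy) ** 2 <= r**2
    if cylinder_mask:
        dens = np.where(mask, dens, 0.0)
    return dens, mask


def extract_mesh(field_or_fn, aabb: Aabb, cfg: MeshConfig) -> Mesh:
    """Marching-Cubes isosurface of the density field at ``sigma_threshold``.

    Vertices are mapped from voxel indices to metric world coordinates. An
    empty isosurface yields an empty mesh (not an error). Vertex colors, when
    requested, query the color branch with the outward vertex normal as the
    view direction.
    """
    res = cfg.grid_resolution
    dens, _ = sample_density_grid(field_or_fn, aabb, res, cfg.cylinder_mask)
    level = cfg.sigma_threshold
    if dens.max() <= level or dens.min() >= level:
        return Mesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
    spacing = aabb.size / (res - 1)
    verts, faces, normals, _ = marching_cubes(dens, level=level, spacing=tuple(spacing))
    verts = verts + aabb.min_corner
    colors = None
    if cfg.with_colors and isinstance(field_or_fn, RadianceField):
        n = normals / np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-9)
        colors = field_or_fn.query_color(verts, n)
    return Mesh(verts, faces.astype(int), colors)


def mesh_height(mesh: Mesh) -> float:
    """Plant height: max minus min of the mesh's z coordinates, meters."""
    if mesh.is_empty:
        raise ValueError("cannot measure the height of an empty mesh")
    z = mesh.vertices[:, 2]
    return float(z.max() - z.min())


def save_mesh(mesh: Mesh, path) -> None:
    """Write OBJ or PLY (by extension) via trimesh."""
    import trimesh

    tm = trimesh.Trimesh(
        vertices=mesh.vertices,
        faces=mesh.faces,
        vertex_colors=None
        if mesh.vertex_colors is None
        else (np.clip(mesh.vertex_colors, 0, 1) * 255).astype(np.uint8),
        process=False,
    )
    tm.export(path)
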