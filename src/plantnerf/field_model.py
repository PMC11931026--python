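"""The radiance-field representation: multi-resolution hash encodings, shallow
density/color MLPs, and per-image exposure and pose-offset parameters.

The field maps (position, view direction) -> (color, density). Positions are
encoded with a multi-resolution hash grid (16 levels, 2^19-entry tables, 2
features per entry, resolutions in geometric progression from 16 to a 2048
finest grid); view directions with a low-order frequency encoding. A
one-hidden-layer density MLP emits a non-negative density (exponential
activation, the standard pairing with hash encodings) plus a
15-dimensional geometric feature; a two-hidden-layer color MLP consumes the
16-dimensional geometric feature (raw density prepended to the 15 features)
together with the direction encoding and emits sigmoid RGB.

A separate, much smaller "coarse" field (8 hash levels up to resolution 512,
one hidden layer, view-independent color) drives hierarchical ray sampling.

Everything is plain numpy with hand-derived backward passes: each forward
returns a cache, and the matching ``*_backward`` consumes it. Hash-table
gradients are accumulated with ``np.bincount`` scatter-adds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field as dc_field

import numpy as np

from .geometry import Aabb, Pose, so3_exp

__all__ = [
    "HashGridConfig",
    "FieldConfig",
    "RadianceField",
    "hash_encode",
    "encode_direction",
    "density_net",
    "color_net",
    "DIR_ENC_DIM",
]

_HASH_PRIMES = np.array([1, 2654435761, 805459861], dtype=np.int64)

#: frequency encoding [d, sin(2^j pi d), cos(2^j pi d) for j=0..3] per component
DIR_N_FREQS = 4
DIR_ENC_DIM = 3 + 2 * 3 * DIR_N_FREQS  # 27

# corner offsets of a unit cell, shape (8, 3)
_CORNERS = np.array(
    [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=np.int64
)


@dataclass(frozen=True)
class HashGridConfig:
    """Multi-resolution hash grid parameters (Instant-NGP style)."""

    n_levels: int = 16
    log2_table_size: int = 19
    features_per_entry: int = 2
    coarsest: int = 16
    finest: int = 2048

    @property
    def table_size(self) -> int:
        return 1 << self.log2_table_size

    @property
    def feature_dim(self) -> int:
        return self.n_levels * self.features_per_entry

    def level_resolutions(self) -> np.ndarray:
        """N_l = floor(N_min * b**l) with b chosen so N_0 = coarsest and
        N_{L-1} = finest exactly."""
        L = self.n_levels
        if L == 1:
            return np.array([self.coarsest])
        b = np.exp((np.log(self.finest) - np.log(self.coarsest)) / (L - 1))
        return np.floor(self.coarsest * b ** np.arange(L) + 1e-9).astype(int)

    def level_table_sizes(self) -> list[int]:
        return [
            int(min((r + 1) ** 3, self.table_size)) for r in self.level_resolutions()
        ]

    def level_offsets(self) -> np.ndarray:
        """Row offsets of each level inside the packed table."""
        return np.concatenate([[0], np.cumsum(self.level_table_sizes())])


#: small density-only-grade grid for the coarse sampling field
COARSE_GRID = HashGridConfig(
    n_levels=8, log2_table_size=15, features_per_entry=2, coarsest=16, finest=512
)


def _init_table(cfg: HashGridConfig, rng: np.random.Generator, dtype) -> np.ndarray:
    """Packed table: all levels concatenated, shape (sum_l T_l, F)."""
    total = int(cfg.level_offsets()[-1])
    return rng.uniform(-1e-4, 1e-4, size=(total, cfg.features_per_entry)).astype(dtype)


def _packed_indices(cfg: HashGridConfig):
    """Precomputed per-level index helpers (cached on the config object)."""
    cached = _INDEX_CACHE.get(cfg)
    if cached is None:
        res = cfg.level_resolutions()
        dense = (res + 1) ** 3 <= cfg.table_size
        offsets = cfg.level_offsets()[:-1]
        cached = (res, dense, offsets)
        _INDEX_CACHE[cfg] = cached
    return cached


_INDEX_CACHE: dict = {}


def hash_encode(
    x01: np.ndarray,
    cfg: HashGridConfig,
    table: np.ndarray,
    need_input_grad: bool = False,
):
    """Trilinear multi-resolution hash encoding of points in [0, 1]^3.

    Out-of-box points are clamped. Levels whose dense grid fits in the table
    are indexed directly; finer levels through the spatial hash (coordinates
    times large primes, XOR-combined, modulo table size). Returns
    ``(features (N, L*F), cache)`` for :func:`hash_encode_backward`.
    """
    from . import _hash_kernels

    res, dense, offsets = _packed_indices(cfg)
    x = np.clip(np.ascontiguousarray(x01, dtype=float), 0.0, 1.0)
    n = len(x)
    L = cfg.n_levels
    F = cfg.features_per_entry
    out = np.zeros((n, L * F), dtype=table.dtype)
    idx = np.empty((n, L, 8), dtype=np.int32)  # packed tables stay < 2^31 rows
    w = np.empty((n, L, 8), dtype=table.dtype)
    frac = np.empty((n, L, 3) if need_input_grad else (1, 1, 3))
    _hash_kernels.encode_fwd(
        x,
        res.astype(np.int64),
        dense,
        offsets.astype(np.int64),
        np.int64(cfg.table_size - 1),
        table,
        out,
        idx,
        w,
        frac,
        need_input_grad,
    )
    cache = {
        "idx": idx,
        "w": w,
        "frac": frac,
        "table": table,
        "cfg": cfg,
        "res": res,
        "need_dx": need_input_grad,
    }
    return out, cache


def hash_encode_backward(cache, grad_out: np.ndarray):
    """Backward of :func:`hash_encode`.

    Returns ``(packed table gradient, grad_x01)``; ``grad_x01`` is None
    unless the forward was called with ``need_input_grad=True``.
    """
    from . import _hash_kernels

    table = cache["table"]
    n = grad_out.shape[0]
    tgrad = np.zeros_like(table, dtype=table.dtype)
    gx = np.zeros((n, 3) if cache["need_dx"] else (1, 3))
    _hash_kernels.encode_bwd(
        np.ascontiguousarray(grad_out, dtype=table.dtype),
        cache["idx"],
        cache["w"],
        cache["frac"],
        table,
        cache["res"].astype(np.int64),
        tgrad,
        gx,
        cache["need_dx"],
    )
    return tgrad, (gx if cache["need_dx"] else None)


def encode_direction(d: np.ndarray, with_grad_cache: bool = False):
    """Frequency encoding of unit view directions.

    Layout per direction: ``[d, sin(2^j pi d), cos(2^j pi d)]`` for
    ``j = 0..3``, giving 3 + 24 = 27 dimensions.
    """
    d = np.atleast_2d(np.asarray(d, dtype=float))
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero view direction")
    freqs = (2.0 ** np.arange(DIR_N_FREQS)) * np.pi  # (J,)
    ang = d[:, None, :] * freqs[None, :, None]  # (N, J, 3)
    enc = np.concatenate(
        [d, np.sin(ang).reshape(len(d), -1), np.cos(ang).reshape(len(d), -1)], axis=1
    )
    if not with_grad_cache:
        return enc
    return enc, {"d": d, "freqs": freqs, "ang": ang}


def encode_direction_backward(cache, grad_enc: np.ndarray) -> np.ndarray:
    """Gradient of :func:`encode_direction` with respect to the direction."""
    d, freqs, ang = cache["d"], cache["freqs"], cache["ang"]
    n = len(d)
    J = len(freqs)
    g_raw = grad_enc[:, :3]
    g_sin = grad_enc[:, 3 : 3 + 3 * J].reshape(n, J, 3)
    g_cos = grad_enc[:, 3 + 3 * J :].reshape(n, J, 3)
    g = g_raw + np.einsum("njc,j->nc", g_sin * np.cos(ang) - g_cos * np.sin(ang), freqs)
    return g


# ---------------------------------------------------------------------------
# tiny MLP machinery


def _relu(z):
    return np.maximum(z, 0.0)


def _softplus(z):
    return np.logaddexp(0.0, z)


# density activation: exponential (the standard choice with hash encodings --
# multiplicative updates reach fully opaque densities quickly), clamped for
# numerical safety. Derivative equals the activation below the clamp.
_RAW_SIGMA_MAX = 8.0  # sigma <= e^8 ~ 3 x 10^3 per meter


def _density_act(raw):
    return np.exp(np.minimum(raw, _RAW_SIGMA_MAX))


def _density_act_grad(raw, sigma):
    return np.where(raw < _RAW_SIGMA_MAX, sigma, 0.0)


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _elu(z):
    return np.where(z > 0, z, np.expm1(np.minimum(z, 0.0)))


def _linear_init(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))


@dataclass(frozen=True)
class FieldConfig:
    """Architecture hyperparameters of the radiance field."""

    fine_grid: HashGridConfig = dc_field(default_factory=HashGridConfig)
    coarse_grid: HashGridConfig = dc_field(default_factory=lambda: COARSE_GRID)
    density_hidden: int = 64
    color_hidden: int = 64
    coarse_hidden: int = 32
    geo_features: int = 15


class RadianceField:
    """Trainable scene state: hash tables, MLPs, exposures, pose offsets.

    ``scene_box`` is the axis-aligned region over which hash coordinates are
    normalized; it must contain every point the renderer can sample (the ROI
    box dilated by the maximum ray length).
    """

    def __init__(
        self,
        config: FieldConfig,
        n_images: int,
        scene_box: Aabb,
        roi_box: Aabb | None = None,
        seed: int = 0,
        dtype=np.float32,
    ):
        self.config = config
        self.n_images = int(n_images)
        self.scene_box = scene_box
        self.roi_box = roi_box if roi_box is not None else scene_box
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        c = config
        geo = c.geo_features
        dt = self.dtype

        def lin(n_in, n_out):
            return _linear_init(rng, n_in, n_out).astype(dt)

        p: dict[str, np.ndarray] = {}
        p["fine_hash"] = _init_table(c.fine_grid, rng, dt)
        p["coarse_hash"] = _init_table(c.coarse_grid, rng, dt)
        p["fine_density_W0"] = lin(c.fine_grid.feature_dim, c.density_hidden)
        p["fine_density_b0"] = np.zeros(c.density_hidden, dt)
        p["fine_density_W1"] = lin(c.density_hidden, 1 + geo)
        p["fine_density_b1"] = np.zeros(1 + geo, dt)
        color_in = 1 + geo + DIR_ENC_DIM
        p["fine_color_W0"] = lin(color_in, c.color_hidden)
        p["fine_color_b0"] = np.zeros(c.color_hidden, dt)
        p["fine_color_W1"] = lin(c.color_hidden, c.color_hidden)
        p["fine_color_b1"] = np.zeros(c.color_hidden, dt)
        p["fine_color_W2"] = lin(c.color_hidden, 3)
        p["fine_color_b2"] = np.zeros(3, dt)
        p["coarse_W0"] = lin(c.coarse_grid.feature_dim, c.coarse_hidden)
        p["coarse_b0"] = np.zeros(c.coarse_hidden, dt)
        p["coarse_W1"] = lin(c.coarse_hidden, 4)
        p["coarse_b1"] = np.zeros(4, dt)
        p["exposure"] = np.zeros(self.n_images)
        p["pose_dt"] = np.zeros((self.n_images, 3))
        p["pose_dtheta"] = np.zeros((self.n_images, 3))
        p["background_raw"] = np.zeros(3)
        self.params = p

    def param_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    @property
    def background(self) -> np.ndarray:
        return _sigmoid(self.params["background_raw"])

    def normalize(self, x_world: np.ndarray) -> np.ndarray:
        box = self.scene_box
        return (np.atleast_2d(x_world) - box.min_corner) / box.size

    def refined_pose(self, base: Pose, image_index: int) -> Pose:
        """Base camera-to-world pose with the learned per-image offset applied."""
        c2w = base.as_c2w()
        dth = self.params["pose_dtheta"][image_index]
        dt = self.params["pose_dt"][image_index]
        return Pose(so3_exp(dth) @ c2w.rotation, c2w.translation + dt, "c2w")

    # -- fine field --------------------------------------------------------

    def fine_forward(
        self, x01: np.ndarray, denc: np.ndarray | None, need_input_grad: bool = False
    ):
        """Density (+ color when ``denc`` given) of the fine field.

        Returns ``(sigma (P,), rgb (P, 3) | None, cache)``.
        """
        p = self.params
        enc, hcache = hash_encode(x01, self.config.fine_grid, p["fine_hash"], need_input_grad)
        z0 = enc @ p["fine_density_W0"] + p["fine_density_b0"]
        h0 = _relu(z0)
        z1 = h0 @ p["fine_density_W1"] + p["fine_density_b1"]
        raw = z1[:, 0]
        sigma = _density_act(raw)
        cache = {"hcache": hcache, "enc": enc, "z0": z0, "h0": h0, "z1": z1, "denc": denc}
        if denc is None:
            return sigma, None, cache
        geo = _elu(z1[:, 1:])
        geo16 = np.concatenate([raw[:, None], geo], axis=1)
        cin = np.concatenate([geo16, denc.astype(z1.dtype, copy=False)], axis=1)
        y0 = _relu(cin @ p["fine_color_W0"] + p["fine_color_b0"])
        y1 = _relu(y0 @ p["fine_color_W1"] + p["fine_color_b1"])
        z2 = y1 @ p["fine_color_W2"] + p["fine_color_b2"]
        rgb = _sigmoid(z2)
        cache.update({"geo": geo, "cin": cin, "y0": y0, "y1": y1, "rgb": rgb})
        return sigma, rgb, cache

    def fine_backward(
        self,
        cache,
        g_sigma: np.ndarray,
        g_rgb: np.ndarray | None,
        grads: dict[str, np.ndarray],
    ):
        """Backward of :meth:`fine_forward`; accumulates into ``grads``.

        Returns ``(grad_x01 | None, grad_denc | None)``.
        """
        p = self.params
        z1 = cache["z1"]
        raw = z1[:, 0]
        g_sigma = np.asarray(g_sigma, dtype=z1.dtype)
        if g_rgb is not None:
            g_rgb = np.asarray(g_rgb, dtype=z1.dtype)
        g_z1 = np.zeros_like(z1)
        g_denc = None
        if g_rgb is not None:
            rgb, y1, y0, cin = cache["rgb"], cache["y1"], cache["y0"], cache["cin"]
            g_z2 = g_rgb * rgb * (1.0 - rgb)
            grads["fine_color_W2"] += y1.T @ g_z2
            grads["fine_color_b2"] += g_z2.sum(0)
            g_y1 = (g_z2 @ p["fine_color_W2"].T) * (y1 > 0)
            grads["fine_color_W1"] += y0.T @ g_y1
            grads["fine_color_b1"] += g_y1.sum(0)
            g_y0 = (g_y1 @ p["fine_color_W1"].T) * (y0 > 0)
            grads["fine_color_W0"] += cin.T @ g_y0
            grads["fine_color_b0"] += g_y0.sum(0)
            g_cin = g_y0 @ p["fine_color_W0"].T
            n_geo16 = 1 + self.config.geo_features
            g_geo16 = g_cin[:, :n_geo16]
            g_denc = g_cin[:, n_geo16:]
            g_z1[:, 0] += g_geo16[:, 0]
            # elu'(z) = 1 for z > 0 else exp(z) = elu + 1
            g_z1[:, 1:] += g_geo16[:, 1:] * np.where(z1[:, 1:] > 0, 1.0, cache["geo"] + 1.0)
        g_z1[:, 0] += g_sigma * _density_act_grad(raw, _density_act(raw))
        h0, z0, enc = cache["h0"], cache["z0"], cache["enc"]
        grads["fine_density_W1"] += h0.T @ g_z1
        grads["fine_density_b1"] += g_z1.sum(0)
        g_h0 = (g_z1 @ p["fine_density_W1"].T) * (z0 > 0)
        grads["fine_density_W0"] += enc.T @ g_h0
        grads["fine_density_b0"] += g_h0.sum(0)
        g_enc = g_h0 @ p["fine_density_W0"].T
        table_grad, grad_x = hash_encode_backward(cache["hcache"], g_enc)
        grads["fine_hash"] += table_grad
        return grad_x, g_denc

    # -- coarse field ------------------------------------------------------

    def coarse_forward(self, x01: np.ndarray, need_input_grad: bool = False):
        """Density and view-independent color of the coarse sampling field."""
        p = self.params
        enc, hcache = hash_encode(
            x01, self.config.coarse_grid, p["coarse_hash"], need_input_grad
        )
        z0 = enc @ p["coarse_W0"] + p["coarse_b0"]
        h0 = _relu(z0)
        z1 = h0 @ p["coarse_W1"] + p["coarse_b1"]
        sigma = _density_act(z1[:, 0])
        rgb = _sigmoid(z1[:, 1:])
        cache = {"hcache": hcache, "enc": enc, "z0": z0, "h0": h0, "z1": z1, "rgb": rgb}
        return sigma, rgb, cache

    def coarse_backward(self, cache, g_sigma, g_rgb, grads):
        p = self.params
        z1, rgb = cache["z1"], cache["rgb"]
        g_sigma = np.asarray(g_sigma, dtype=z1.dtype)
        g_rgb = np.asarray(g_rgb, dtype=z1.dtype)
        g_z1 = np.empty_like(z1)
        g_z1[:, 0] = g_sigma * _density_act_grad(z1[:, 0], _density_act(z1[:, 0]))
        g_z1[:, 1:] = g_rgb * rgb * (1.0 - rgb)
        h0, z0, enc = cache["h0"], cache["z0"], cache["enc"]
        grads["coarse_W1"] += h0.T @ g_z1
        grads["coarse_b1"] += g_z1.sum(0)
        g_h0 = (g_z1 @ p["coarse_W1"].T) * (z0 > 0)
        grads["coarse_W0"] += enc.T @ g_h0
        grads["coarse_b0"] += g_h0.sum(0)
        g_enc = g_h0 @ p["coarse_W0"].T
        table_grad, grad_x = hash_encode_backward(cache["hcache"], g_enc)
        grads["coarse_hash"] += table_grad
        return grad_x

    # -- convenience queries (no gradients) --------------------------------

    def query_density(self, x_world: np.ndarray, chunk: int = 262144) -> np.ndarray:
        """Fine-field density at world points, evaluated in chunks."""
        x_world = np.atleast_2d(x_world)
        out = np.empty(len(x_world))
        for s in range(0, len(x_world), chunk):
            sl = slice(s, s + chunk)
            sigma, _, _ = self.fine_forward(self.normalize(x_world[sl]), None)
            out[sl] = sigma
        return out

    def query_color(self, x_world: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        """Fine-field color at world points for given unit view directions."""
        denc = encode_direction(np.atleast_2d(dirs))
        _, rgb, _ = self.fine_forward(self.normalize(x_world), denc)
        return rgb

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "config": asdict(self.config),
            "n_images": self.n_images,
            "scene_box": [self.scene_box.min_corner.tolist(), self.scene_box.max_corner.tolist()],
            "roi_box": [self.roi_box.min_corner.tolist(), self.roi_box.max_corner.tolist()],
        }
        np.savez(path, __meta__=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path) -> "RadianceField":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        cfgd = dict(meta["config"])
        cfgd["fine_grid"] = HashGridConfig(**cfgd["fine_grid"])
        cfgd["coarse_grid"] = HashGridConfig(**cfgd["coarse_grid"])
        config = FieldConfig(**cfgd)
        field = cls(
            config,
            n_images=meta["n_images"],
            scene_box=Aabb(*[np.array(c) for c in meta["scene_box"]]),
            roi_box=Aabb(*[np.array(c) for c in meta["roi_box"]]),
        )
        for k in field.params:
            field.params[k] = data[k]
        field.dtype = field.params["fine_hash"].dtype
        return field


# ---------------------------------------------------------------------------
# thin functional wrappers


def density_net(field: RadianceField, x_enc: np.ndarray):
    """Density branch on hash-encoded inputs: ``(sigma (P,), geo (P, 15))``."""
    p = field.params
    h0 = _relu(np.atleast_2d(x_enc) @ p["fine_density_W0"] + p["fine_density_b0"])
    z1 = h0 @ p["fine_density_W1"] + p["fine_density_b1"]
    return _density_act(z1[:, 0]), _elu(z1[:, 1:])


def color_net(field: RadianceField, geo16: np.ndarray, d_enc: np.ndarray) -> np.ndarray:
    """Color branch: 16-dim geometric feature + direction encoding -> RGB."""
    p = field.params
    cin = np.concatenate([np.atleast_2d(geo16), np.atleast_2d(d_enc)], axis=1)
    y0 = _relu(cin @ p["fine_color_W0"] + p["fine_color_b0"])
    y1 = _relu(y0 @ p["fine_color_W1"] + p["fine_color_b1"])
    return _sigmoid(y1 @ p["fine_color_W2"] + p["fine_color_b2"])
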