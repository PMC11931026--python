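"""ROI-constrained hierarchical ray sampling, volume rendering, and training.

Rays are intersected with the ROI bounding box by the slab method; the hit
interval (0, t_max] and the remainder (t_max, t_b] (t_b = maximum ray length)
are sampled with different densities so most coarse samples land where the
plant is. Coarse-field densities convert to compositing weights

    w_i = T_i (1 - exp(-sigma_i * delta_i)),   T_i = exp(-sum_{j<i} sigma_j delta_j)

whose normalization is a piecewise-constant PDF along the ray; inverse
transform sampling of that PDF places the fine samples. Colors are composited
front to back with the residual transmittance falling onto a (learnable)
background color.

Training minimizes the MSE between exposure-adjusted rendered colors and the
observed pixels, summed over the coarse and fine renders, plus L2 penalties
on the per-image exposure rates and pose offsets. All gradients — hash
tables, MLPs, exposures, pose offsets (through the ray geometry), background
— are computed by the hand-written backward passes in this module and in
:mod:`plantnerf.field_model`, and applied with Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .geometry import (
    Aabb,
    Intrinsics,
    Pose,
    camera_ray_directions,
    so3_exp,
    so3_right_jacobian,
)
from .field_model import (
    FieldConfig,
    RadianceField,
    encode_direction,
    encode_direction_backward,
)

__all__ = [
    "Ray",
    "RayInterval",
    "SampleBatch",
    "TrainConfig",
    "ray_aabb_intersect",
    "sample_two_regions",
    "coarse_weights",
    "inverse_transform_sample",
    "volume_render",
    "apply_exposure",
    "apply_pose_offset",
    "train",
    "render_view",
]


@dataclass(frozen=True)
class Ray:
    origin: np.ndarray
    direction: np.ndarray
    image_id: int = 0
    pixel: tuple = (0, 0)

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("ray direction must be unit length")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class RayInterval:
    """Parametric ROI interval of a ray: [t_min, t_max] within [0, t_b]."""

    t_min: float
    t_max: float
    t_b: float
    hit: bool


@dataclass(frozen=True)
class SampleBatch:
    """Per-ray sample bookkeeping for hierarchical sampling."""

    t: np.ndarray
    deltas: np.ndarray
    sigmas: np.ndarray
    transmittance: np.ndarray
    weights: np.ndarray
    weights_norm: np.ndarray
    t_b: float
    fallback_uniform: bool = False


# ---------------------------------------------------------------------------
# geometry


def _intersect_aabb_batch(o: np.ndarray, d: np.ndarray, box: Aabb):
    """Vectorized slab test. Returns (hit, t_min_clamped, t_max)."""
    o = np.atleast_2d(o)
    d = np.atleast_2d(d)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (box.min_corner - o) / d
        t2 = (box.max_corner - o) / d
    lo = np.minimum(t1, t2)
    hi = np.maximum(t1, t2)
    # zero direction components: inside the slab -> unbounded, else empty
    degen = np.abs(d) < 1e-300
    if degen.any():
        inside = (o >= box.min_corner) & (o <= box.max_corner)
        lo = np.where(degen, np.where(inside, -np.inf, np.inf), lo)
        hi = np.where(degen, np.where(inside, np.inf, -np.inf), hi)
    t_min = lo.max(axis=1)
    t_max = hi.min(axis=1)
    hit = (t_min <= t_max) & (t_max >= 0)
    return hit, np.clip(t_min, 0.0, None), t_max


def ray_aabb_intersect(ray: Ray, box: Aabb, t_b: float | None = None) -> RayInterval:
    """Slab-method ray/ROI-box intersection.

    On a hit, ``t_min`` is clamped to 0 (cameras sit inside the box by rig
    construction, so the near intersection is behind or at the camera).
    """
    hit, t_min, t_max = _intersect_aabb_batch(ray.origin[None], ray.direction[None], box)
    if t_b is None:
        t_b = 2.0 * box.diagonal
    return RayInterval(
        t_min=float(t_min[0]),
        t_max=float(min(t_max[0], t_b)) if hit[0] else 0.0,
        t_b=float(t_b),
        hit=bool(hit[0]),
    )


# ---------------------------------------------------------------------------
# sampling


def _stratified(lo, hi, n, rng=None):
    """Stratified samples in (lo, hi] per ray; midpoints when rng is None.

    ``lo``/``hi`` are (B,) arrays, output (B, n).
    """
    lo = np.atleast_1d(np.asarray(lo, dtype=float))
    hi = np.atleast_1d(np.asarray(hi, dtype=float))
    B = len(lo)
    if rng is None:
        u = np.full((B, n), 0.5)
    else:
        u = rng.random((B, n))
    j = np.arange(n)[None, :]
    return lo[:, None] + (j + u) / n * (hi - lo)[:, None]


def sample_two_regions(
    iv: RayInterval,
    n_c: int,
    roi_fraction: float = 0.75,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Coarse t-values: denser in the ROI interval, sparser beyond it.

    ``round(roi_fraction * n_c)`` jittered-stratified samples in (0, t_max],
    the rest in (t_max, t_b]; a miss gets background-only sampling in
    (0, t_b]. Pass ``rng=None`` to disable jitter (stratum midpoints).
    """
    if not 0 < roi_fraction < 1:
        raise ValueError("roi_fraction must be in (0, 1)")
    if not iv.hit or iv.t_max <= 0:
        return np.sort(_stratified([0.0], [iv.t_b], n_c, rng)[0])
    n_roi = int(round(roi_fraction * n_c))
    n_bg = n_c - n_roi
    parts = [_stratified([0.0], [iv.t_max], n_roi, rng)[0]]
    if n_bg:
        parts.append(_stratified([iv.t_max], [iv.t_b], n_bg, rng)[0])
    return np.sort(np.concatenate(parts))


def _sample_coarse_batch(hit, t_max, t_b, n_c, roi_fraction, rng):
    """Vectorized two-region sampling, (B, n_c) sorted t-values."""
    n_roi = int(round(roi_fraction * n_c))
    n_bg = n_c - n_roi
    B = len(t_max)
    eff_hit = hit & (t_max > 0)
    tm = np.where(eff_hit, t_max, t_b)
    roi = _stratified(np.zeros(B), tm, n_roi, rng)
    if n_bg:
        bg_lo = np.where(eff_hit, tm, 0.0)
        # miss rays: spread the remaining samples over the full (0, t_b] too
        bg = _stratified(bg_lo, np.full(B, t_b), n_bg, rng)
        t = np.concatenate([roi, bg], axis=1)
    else:
        t = roi
    return np.sort(t, axis=1)


def _deltas(t: np.ndarray, t_b: float) -> np.ndarray:
    """delta_i = t_{i+1} - t_i, closing the last bin at t_b."""
    t = np.atleast_2d(t)
    return np.diff(t, axis=1, append=np.full((t.shape[0], 1), t_b))


def _weights_batch(sigmas: np.ndarray, deltas: np.ndarray):
    """Compositing weights and transmittances from densities (batched)."""
    tau = sigmas * deltas
    one_m = np.exp(-tau)  # per-bin survival
    alpha = -np.expm1(-tau)
    T = np.cumprod(one_m, axis=1)
    T = np.concatenate([np.ones((T.shape[0], 1)), T[:, :-1]], axis=1)
    w = T * alpha
    t_res = T[:, -1] * one_m[:, -1]
    return w, T, t_res, alpha, one_m

def coarse_weights(
    sigmas: np.ndarray, t_values: np.ndarray, t_b: float | None = None
) -> SampleBatch:
    """Per-sample compositing weights w_i = T_i (1 - exp(-sigma_i delta_i)).

    The printed form of this rule omits the minus sign in the exponential,
    which would make weights negative; the standard absorption form is used.
    Normalized weights are the sampling PDF; when every weight is zero the
    PDF falls back to uniform (flagged).
    """
    t = np.asarray(t_values, dtype=float).reshape(-1)
    sig = np.asarray(sigmas, dtype=float).reshape(-1)
    if np.any(sig < 0):
        raise ValueError("densities must be non-negative")
    if np.any(np.diff(t) < 0):
        raise ValueError("t_values must be sorted")
    if t_b is None:
        t_b = float(t[-1] + (np.median(np.diff(t)) if len(t) > 1 else 0.0))
    d = _deltas(t[None], float(t_b))[0]
    w, T, _, _, _ = _weights_batch(sig[None], d[None])
    w, T = w[0], T[0]
    total = w.sum()
    fallback = total <= 0
    w_hat = np.full_like(w, 1.0 / len(w)) if fallback else w / total
    return SampleBatch(
        t=t,
        deltas=d,
        sigmas=sig,
        transmittance=T,
        weights=w,
        weights_norm=w_hat,
        t_b=float(t_b),
        fallback_uniform=bool(fallback),
    )


def _normalize_weights_batch(w: np.ndarray) -> np.ndarray:
    total = w.sum(axis=1, keepdims=True)
    uniform = np.full_like(w, 1.0 / w.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        w_hat = np.where(total > 0, w / np.where(total > 0, total, 1.0), uniform)
    return w_hat


def _its_batch(edges: np.ndarray, w_hat: np.ndarray, n_f: int, rng=None, u=None):
    """Inverse-transform samples from per-ray piecewise-constant PDFs.

    ``edges`` is (B, S+1) bin boundaries, ``w_hat`` (B, S) probabilities.
    ``u`` overrides the uniform draws (used for deterministic rendering).
    """
    B, S = w_hat.shape
    cdf = np.concatenate([np.zeros((B, 1)), np.cumsum(w_hat, axis=1)], axis=1)
    cdf[:, -1] = 1.0
    if u is None:
        u = rng.random((B, n_f))
    offs = 2.0 * np.arange(B)[:, None]
    flat_cdf = (cdf + offs).ravel()
    pos = np.searchsorted(flat_cdf, (u + offs).ravel(), side="right") - 1
    bins = np.clip(pos - np.repeat(np.arange(B), n_f) * (S + 1), 0, S - 1)
    rows = np.repeat(np.arange(B), n_f)
    width = w_hat[rows, bins]
    frac = np.where(width > 0, (u.ravel() - cdf[rows, bins]) / np.where(width > 0, width, 1.0), 0.5)
    t = edges[rows, bins] + np.clip(frac, 0.0, 1.0) * (edges[rows, bins + 1] - edges[rows, bins])
    return t.reshape(B, n_f)


def inverse_transform_sample(
    batch: SampleBatch, n_f: int, seed: int = 0, merge: bool = True
) -> np.ndarray:
    """Draw ``n_f`` fine t-values from the coarse-weight PDF of one ray.

    With ``merge=True`` (default) the fine samples are merged and sorted with
    the coarse t-values, yielding the fine-network input points.
    """
    rng = np.random.default_rng(seed)
    edges = np.concatenate([batch.t, [batch.t_b]])
    t_f = _its_batch(edges[None], batch.weights_norm[None], n_f, rng)[0]
    if not merge:
        return t_f
    return np.sort(np.concatenate([batch.t, t_f]))


# ---------------------------------------------------------------------------
# compositing


def _composite_batch(sigmas, rgbs, deltas, background):
    """Front-to-back emission-absorption compositing (batched).

    Returns (colors (B, 3), weights (B, S), residual transmittance (B,),
    cache for backward).
    """
    w, T, t_res, alpha, one_m = _weights_batch(sigmas, deltas)
    bg = np.asarray(background, dtype=float)
    C = np.einsum("bs,bsc->bc", w, rgbs) + t_res[:, None] * bg
    cache = {
        "w": w,
        "T": T,
        "t_res": t_res,
        "one_m": one_m,
        "rgbs": rgbs,
        "deltas": deltas,
        "bg": bg,
    }
    return C, w, t_res, cache


def _composite_backward(cache, g_C):
    """Gradients of the composited color w.r.t. densities, colors, background."""
    w, T, t_res = cache["w"], cache["T"], cache["t_res"]
    one_m, rgbs, deltas, bg = cache["one_m"], cache["rgbs"], cache["deltas"], cache["bg"]
    g_rgb = w[..., None] * g_C[:, None, :]
    # suffix_i = sum_{j>i} w_j c_j + t_res * bg  (everything attenuated by bin i)
    wc = w[..., None] * rgbs
    suffix = np.flip(np.cumsum(np.flip(wc, axis=1), axis=1), axis=1) - wc
    suffix = suffix + (t_res[:, None] * bg)[:, None, :]
    g_sigma = deltas * np.einsum(
        "bsc,bc->bs", (one_m * T)[..., None] * rgbs - suffix, g_C
    )
    g_bg = (t_res[:, None] * g_C).sum(axis=0)
    return g_sigma, g_rgb, g_bg


def volume_render(
    sigmas: np.ndarray,
    colors: np.ndarray,
    t_values: np.ndarray,
    background,
    t_b: float | None = None,
):
    """Composite one ray's samples onto a background color.

    Returns ``(pixel rgb, per-sample weights)``; weights plus the residual
    transmittance sum to 1.
    """
    t = np.asarray(t_values, dtype=float).reshape(-1)
    if t_b is None:
        t_b = float(t[-1] + (np.median(np.diff(t)) if len(t) > 1 else 0.0))
    d = _deltas(t[None], float(t_b))
    C, w, _, _ = _composite_batch(
        np.asarray(sigmas, dtype=float)[None],
        np.asarray(colors, dtype=float)[None],
        d,
        background,
    )
    return C[0], w[0]


# ---------------------------------------------------------------------------
# exposure and pose offsets


def apply_exposure(rgb: np.ndarray, E_i: float) -> np.ndarray:
    """Scale a synthesized color by S_i = exp(ln(2) E_i) = 2**E_i."""
    if not np.all(np.isfinite(np.asarray(E_i, dtype=float))):
        raise ValueError("exposure rate must be finite")
    return (2.0**E_i) * np.asarray(rgb, dtype=float)


def apply_pose_offset(pose: Pose, delta_t: np.ndarray, delta_theta: np.ndarray) -> Pose:
    """Left-perturb a camera-to-world pose by a translation and axis-angle offset."""
    c2w = pose.as_c2w()
    R = so3_exp(delta_theta) @ c2w.rotation
    return Pose(R, c2w.translation + np.asarray(delta_t, dtype=float), "c2w").as_convention(
        pose.convention
    )


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    ``n_coarse``/``n_fine`` are samples per ray; ``roi_fraction`` is the share
    of coarse samples placed inside the ROI interval; ``t_b_factor`` sets the
    maximum ray length as a multiple of the ROI diagonal. Learning rates
    follow hash-grid practice (larger for tables than for MLPs).
    """

    n_iters: int = 2000
    batch_rays: int = 512
    n_coarse: int = 64
    n_fine: int = 128
    roi_fraction: float = 0.75
    # maximum ray length as a multiple of the ROI diagonal. Hash coordinates
    # are normalized over the ROI dilated by t_b, so a long reach dilutes the
    # encoding's effective resolution at the plant; 1.2 x diagonal spans the
    # whole box from any camera while keeping the ROI a useful fraction of
    # the normalized volume (the far background is a learnable constant).
    t_b_factor: float = 1.2
    lr_hash: float = 1e-2
    lr_mlp: float = 1e-3
    # exposure needs a faster time-scale than the color MLP, or view-dependent
    # color slowly absorbs per-image brightness before E_i can claim it
    lr_exposure: float = 5e-2
    # pose offsets see mostly-noise gradients once poses are right; under
    # Adam they random-walk ~lr * sqrt(iters), while genuine corrections
    # accumulate ~lr * iters. A small lr keeps the walk at millimeters and
    # still reaches degree/centimeter-scale corrections within a run.
    lr_pose: float = 2e-4
    lr_background: float = 5e-2
    lambda_exposure: float = 1e-4
    lambda_pose: float = 1e-4
    # optional penalty on per-ray total opacity 1 - exp(-sum sigma*delta):
    # empty space becomes the preferred explanation of background-colored
    # pixels. Off by default: under Adam's per-parameter step normalization a
    # constant-sign pull also caps converged surface densities, which harms
    # isosurface extraction more than residual fog does.
    lambda_sparsity: float = 0.0
    optimize_exposure: bool = True
    optimize_poses: bool = True
    adam_beta1: float = 0.9
    adam_beta2: float = 0.99
    adam_eps: float = 1e-15
    log_every: int = 50
    field: FieldConfig = dc_field(default_factory=FieldConfig)


def _lr_for(name: str, cfg: TrainConfig) -> float:
    if "hash" in name:
        return cfg.lr_hash
    if name == "exposure":
        return cfg.lr_exposure if cfg.optimize_exposure else 0.0
    if name.startswith("pose_"):
        return cfg.lr_pose if cfg.optimize_poses else 0.0
    if name == "background_raw":
        return cfg.lr_background
    return cfg.lr_mlp


class _Adam:
    def __init__(self, params: dict, cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        cfg = self.cfg
        self.t += 1
        b1, b2 = cfg.adam_beta1, cfg.adam_beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for k, g in grads.items():
            lr = _lr_for(k, cfg)
            if lr == 0.0:
                continue
            m = self.m[k] = b1 * self.m[k] + (1 - b1) * g
            v = self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= lr * (m / c1) / (np.sqrt(v / c2) + cfg.adam_eps)


@dataclass
class _RayBatch:
    """Inputs to one differentiable render-loss evaluation.

    Sample t-values are fixed inputs (sampling is not differentiated
    through), which keeps the loss a smooth function of the parameters.
    """

    img_idx: np.ndarray  # (B,)
    v_cam: np.ndarray  # (B, 3) camera-frame unit directions
    R0: np.ndarray  # (B, 3, 3) base camera-to-world rotations
    C0: np.ndarray  # (B, 3) base camera centers
    obs: np.ndarray  # (B, 3) observed pixel colors
    t_c: np.ndarray  # (B, n_coarse)
    t_f: np.ndarray  # (B, n_coarse + n_fine)
    t_b: float


def _per_image_rotations(field: RadianceField):
    """exp(dtheta_i) and the right Jacobians J_r(dtheta_i), per image."""
    dth = field.params["pose_dtheta"]
    Q = np.stack([so3_exp(v) for v in dth])
    Jr = np.stack([so3_right_jacobian(v) for v in dth])
    return Q, Jr


def _render_loss(field: RadianceField, batch: _RayBatch, cfg: TrainConfig, with_grads=True):
    """Coarse+fine photometric loss and all parameter gradients for a batch."""
    p = field.params
    i = batch.img_idx
    B = len(i)
    Q, Jr = _per_image_rotations(field)
    w_vec = np.einsum("bij,bj->bi", batch.R0, batch.v_cam)
    u = np.einsum("bij,bj->bi", Q[i], w_vec)
    nrm = np.linalg.norm(u, axis=1, keepdims=True)
    d = u / nrm
    o = batch.C0 + p["pose_dt"][i]

    need_dx = with_grads and cfg.optimize_poses
    size = field.scene_box.size

    def eval_field(t, fine: bool):
        x = o[:, None, :] + t[..., None] * d[:, None, :]
        x01 = field.normalize(x.reshape(-1, 3))
        if fine:
            denc, denc_cache = encode_direction(d, with_grad_cache=True)
            denc_pts = np.repeat(denc, t.shape[1], axis=0)
            sig, rgb, cache = field.fine_forward(x01, denc_pts, need_input_grad=need_dx)
            return sig, rgb, cache, denc_cache
        sig, rgb, cache = field.coarse_forward(x01, need_input_grad=need_dx)
        return sig, rgb, cache, None

    S_c = batch.t_c.shape[1]
    S_f = batch.t_f.shape[1]
    sig_c, rgb_c, cache_c, _ = eval_field(batch.t_c, fine=False)
    sig_f, rgb_f, cache_f, denc_cache = eval_field(batch.t_f, fine=True)

    d_c = _deltas(batch.t_c, batch.t_b)
    d_f = _deltas(batch.t_f, batch.t_b)
    bg = field.background
    C_c, _, _, comp_c = _composite_batch(sig_c.reshape(B, S_c), rgb_c.reshape(B, S_c, 3), d_c, bg)
    C_f, _, _, comp_f = _composite_batch(sig_f.reshape(B, S_f), rgb_f.reshape(B, S_f, 3), d_f, bg)

    E = p["exposure"][i]
    S_exp = 2.0**E
    res_f = S_exp[:, None] * C_f - batch.obs
    res_c = S_exp[:, None] * C_c - batch.obs
    tres_f = comp_f["t_res"]
    tres_c = comp_c["t_res"]
    sparsity = np.mean(1.0 - tres_f) + np.mean(1.0 - tres_c)
    loss = float(
        np.mean(res_f**2)
        + np.mean(res_c**2)
        + cfg.lambda_sparsity * sparsity
        + cfg.lambda_exposure * np.sum(p["exposure"] ** 2)
        + cfg.lambda_pose * (np.sum(p["pose_dt"] ** 2) + np.sum(p["pose_dtheta"] ** 2))
    )
    if not with_grads:
        return loss, None

    grads = field.zero_grads()
    norm = 1.0 / res_f.size
    g_Cf = 2.0 * norm * S_exp[:, None] * res_f
    g_Cc = 2.0 * norm * S_exp[:, None] * res_c
    # exposure gradient: dS/dE = ln2 * S
    gE_ray = np.log(2.0) * S_exp * (
        2.0 * norm * np.sum(res_f * C_f + res_c * C_c, axis=1)
    )
    np.add.at(grads["exposure"], i, gE_ray)

    g_sig_f, g_rgb_f, g_bg_f = _composite_backward(comp_f, g_Cf)
    g_sig_c, g_rgb_c, g_bg_c = _composite_backward(comp_c, g_Cc)
    # d(1 - T_res)/d sigma_i = delta_i * T_res
    s_norm = cfg.lambda_sparsity / B
    g_sig_f = g_sig_f + s_norm * d_f * tres_f[:, None]
    g_sig_c = g_sig_c + s_norm * d_c * tres_c[:, None]

    gx_f, g_denc_pts = field.fine_backward(
        cache_f, g_sig_f.reshape(-1), g_rgb_f.reshape(-1, 3), grads
    )
    gx_c = field.coarse_backward(cache_c, g_sig_c.reshape(-1), g_rgb_c.reshape(-1, 3), grads)

    g_bg = g_bg_f + g_bg_c
    grads["background_raw"] += g_bg * bg * (1.0 - bg)

    if need_dx:
        g_xf = (gx_f / size).reshape(B, S_f, 3)
        g_xc = (gx_c / size).reshape(B, S_c, 3)
        g_o = g_xf.sum(axis=1) + g_xc.sum(axis=1)
        g_d = (batch.t_f[..., None] * g_xf).sum(axis=1) + (batch.t_c[..., None] * g_xc).sum(axis=1)
        g_denc = g_denc_pts.reshape(B, S_f, -1).sum(axis=1)
        g_d = g_d + encode_direction_backward(denc_cache, g_denc)
        # through normalization d = u / |u|
        g_u = (g_d - d * np.sum(d * g_d, axis=1, keepdims=True)) / nrm
        np.add.at(grads["pose_dt"], i, g_o)
        # u = Q w  =>  dL/dtheta = J_r^T (w x (Q^T dL/du))
        qg = np.einsum("bji,bj->bi", Q[i], g_u)
        cr = np.cross(w_vec, qg)
        g_th = np.einsum("bji,bj->bi", Jr[i], cr)
        np.add.at(grads["pose_dtheta"], i, g_th)

    grads["exposure"] += 2.0 * cfg.lambda_exposure * p["exposure"]
    grads["pose_dt"] += 2.0 * cfg.lambda_pose * p["pose_dt"]
    grads["pose_dtheta"] += 2.0 * cfg.lambda_pose * p["pose_dtheta"]
    if not cfg.optimize_exposure:
        grads["exposure"][:] = 0.0
    if not cfg.optimize_poses:
        grads["pose_dt"][:] = 0.0
        grads["pose_dtheta"][:] = 0.0
    return loss, grads


def _make_batch(field, cfg, rng, images, R0_all, C0_all, v_cam_all, aabb, t_b):
    """Draw a random ray minibatch and fix its coarse+fine sample t-values."""
    M, H, W, _ = images.shape
    B = cfg.batch_rays
    i = rng.integers(0, M, B)
    pix = rng.integers(0, H * W, B)
    obs = images.reshape(M, -1, 3)[i, pix]
    v_cam = v_cam_all[pix]
    Q, _ = _per_image_rotations(field)
    R0 = R0_all[i]
    C0 = C0_all[i]
    d = np.einsum("bij,bj->bi", Q[i], np.einsum("bij,bj->bi", R0, v_cam))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    o = C0 + field.params["pose_dt"][i]
    hit, _, t_max = _intersect_aabb_batch(o, d, aabb)
    t_max = np.minimum(t_max, t_b)
    t_c = _sample_coarse_batch(hit, t_max, t_b, cfg.n_coarse, cfg.roi_fraction, rng)
    # detached coarse densities drive the fine-sample placement
    x = o[:, None, :] + t_c[..., None] * d[:, None, :]
    sig, _, _ = field.coarse_forward(field.normalize(x.reshape(-1, 3)))
    w, _, _, _, _ = _weights_batch(sig.reshape(B, cfg.n_coarse), _deltas(t_c, t_b))
    w_hat = _normalize_weights_batch(w)
    edges = np.concatenate([t_c, np.full((B, 1), t_b)], axis=1)
    t_fine = _its_batch(edges, w_hat, cfg.n_fine, rng)
    t_f = np.sort(np.concatenate([t_c, t_fine], axis=1), axis=1)
    return _RayBatch(i, v_cam, R0, C0, obs, t_c, t_f, t_b)


def train(
    images: np.ndarray,
    poses: list[Pose],
    intr: Intrinsics,
    aabb: Aabb,
    cfg: TrainConfig | None = None,
    seed: int = 0,
    field: RadianceField | None = None,
    log=None,
) -> tuple[RadianceField, list[tuple[int, float]]]:
    """Fit the radiance field to calibrated, keyframed images.

    ``images`` is (M, H, W, 3) in [0, 1], aligned with ``poses``. Returns the
    trained field and a (iteration, loss) history. ``log`` is an optional
    callable receiving (iteration, loss).
    """
    cfg = cfg or TrainConfig()
    images = np.asarray(images, dtype=float)
    M, H, W, _ = images.shape
    if len(poses) != M:
        raise ValueError("images and poses must align")
    t_b = cfg.t_b_factor * aabb.diagonal
    if field is None:
        scene_box = aabb.dilated(t_b)
        field = RadianceField(cfg.field, M, scene_box, roi_box=aabb, seed=seed)
    R0_all = np.stack([p.R_c2w for p in poses])
    C0_all = np.stack([p.center for p in poses])
    v_cam_all = camera_ray_directions(intr, H, W)
    adam = _Adam(field.params, cfg)
    rng = np.random.default_rng(seed)
    history: list[tuple[int, float]] = []
    for it in range(cfg.n_iters):
        batch = _make_batch(field, cfg, rng, images, R0_all, C0_all, v_cam_all, aabb, t_b)
        loss, grads = _render_loss(field, batch, cfg)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss at iteration {it}: {loss}; "
                f"exposure range [{field.params['exposure'].min():.3g}, "
                f"{field.params['exposure'].max():.3g}]"
            )
        adam.step(field.params, grads)
        if it % cfg.log_every == 0 or it == cfg.n_iters - 1:
            history.append((it, loss))
            if log is not None:
                log(it, loss)
    return field, history


def render_view(
    field: RadianceField,
    pose: Pose,
    intr: Intrinsics,
    h: int,
    w: int,
    cfg: TrainConfig | None = None,
    exposure: float = 0.0,
    background=None,
    chunk: int = 4096,
) -> np.ndarray:
    """Full-frame deterministic render at canonical exposure (E = 0).

    Jitter is disabled (stratum midpoints, stratified inverse-transform
    draws), so repeated renders are bit-identical.
    """
    cfg = cfg or TrainConfig()
    aabb = field.roi_box
    t_b = cfg.t_b_factor * aabb.diagonal
    c2w = pose.as_c2w()
    v_cam = camera_ray_directions(intr, h, w)
    d = v_cam @ c2w.rotation.T
    o = np.broadcast_to(c2w.translation, d.shape)
    bg = field.background if background is None else np.asarray(background, dtype=float)
    out = np.empty((h * w, 3))
    u_det = ((np.arange(cfg.n_fine) + 0.5) / cfg.n_fine)[None, :]
    for s in range(0, h * w, chunk):
        sl = slice(s, min(s + chunk, h * w))
        ob, db = o[sl], d[sl]
        hit, _, t_max = _intersect_aabb_batch(ob, db, aabb)
        t_max = np.minimum(t_max, t_b)
        t_c = _sample_coarse_batch(hit, t_max, t_b, cfg.n_coarse, cfg.roi_fraction, None)
        B = len(ob)
        x = ob[:, None, :] + t_c[..., None] * db[:, None, :]
        sig, _, _ = field.coarse_forward(field.normalize(x.reshape(-1, 3)))
        w_c, _, _, _, _ = _weights_batch(sig.reshape(B, -1), _deltas(t_c, t_b))
        w_hat = _normalize_weights_batch(w_c)
        edges = np.concatenate([t_c, np.full((B, 1), t_b)], axis=1)
        t_fine = _its_batch(edges, w_hat, cfg.n_fine, u=np.broadcast_to(u_det, (B, cfg.n_fine)))
        t_f = np.sort(np.concatenate([t_c, t_fine], axis=1), axis=1)
        xf = ob[:, None, :] + t_f[..., None] * db[:, None, :]
        denc = np.repeat(encode_direction(db), t_f.shape[1], axis=0)
        sigf, rgbf, _ = field.fine_forward(field.normalize(xf.reshape(-1, 3)), denc)
        C, _, _, _ = _composite_batch(
            sigf.reshape(B, -1), rgbf.reshape(B, -1, 3), _deltas(t_f, t_b), bg
        )
        out[sl] = C
    return np.clip((2.0**exposure) * out.reshape(h, w, 3), 0.0, 1.0)
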