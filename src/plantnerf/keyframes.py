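"""Keyframe extraction from two-view orbital video.

The orbital rig records two videos per plant (an upper and a lower camera
ring). Feeding every frame to SfM and the radiance field is wasteful and
blurry frames actively hurt reconstruction, so the pipeline selects a small,
sharp, evenly spread subset:

1. equidistant downsampling to ``target_per_view`` frames per view,
2. rejection of frames whose Laplacian-variance sharpness falls below a
   fraction of the mean over all frames (with a hard quality gate on how many
   removals are tolerable before the capture is declared unusable),
3. seeded random subselection down to ``per_view`` frames per view.

Sharpness is the variance of an 8-neighborhood Laplacian response on the
grayscale image: Var(L) = (1/N) * sum_i (L_i - mu)^2. A constant image scores
exactly 0; blur suppresses high frequencies and hence the variance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "Frame",
    "FrameSet",
    "QualityGateError",
    "laplacian_variance",
    "equidistant_downsample",
    "eliminate_blurry",
    "select_keyframes",
    "extract_keyframes",
]

# 8-neighborhood Laplacian; border handling is replicate padding.
LAPLACIAN_8 = np.array(
    [
        [1.0, 1.0, 1.0],
        [1.0, -8.0, 1.0],
        [1.0, 1.0, 1.0],
    ]
)

# ITU-R BT.601 luma weights for grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


class QualityGateError(RuntimeError):
    """Raised when too many frames are blurry and the capture must be redone."""


@dataclass(frozen=True)
class Frame:
    """A single video frame tagged with its view and source position."""

    pixels: np.ndarray  # H x W x 3 float in [0, 1]
    view_id: str  # "upper" | "lower"
    source_index: int
    sharpness: float

    def __post_init__(self) -> None:
        if self.sharpness < 0:
            raise ValueError("sharpness must be non-negative")


@dataclass(frozen=True)
class FrameSet:
    frames: tuple

    @property
    def per_view_counts(self) -> dict:
        counts: dict = {}
        for f in self.frames:
            counts[f.view_id] = counts.get(f.view_id, 0) + 1
        return counts

    def view(self, view_id: str) -> list:
        return [f for f in self.frames if f.view_id == view_id]

    def __len__(self) -> int:
        return len(self.frames)


def laplacian_variance(image: np.ndarray) -> float:
    """Sharpness score: variance of the 8-neighborhood Laplacian response.

    ``image`` may be grayscale (H x W) or RGB (H x W x 3); RGB is converted
    with BT.601 luma weights first. Borders use replicate padding.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 3:
        gray = image @ _LUMA
    elif image.ndim == 2:
        gray = image
    else:
        raise ValueError("image must be HxW or HxWx3")
    lap = ndimage.convolve(gray, LAPLACIAN_8, mode="nearest")
    return float(lap.var())


def _equidistant_indices(n: int, target: int) -> np.ndarray:
    """Evenly spaced source indices covering first to last frame."""
    if n < target:
        raise ValueError(f"cannot downsample {n} frames to {target}")
    idx = np.round(np.linspace(0, n - 1, target)).astype(int)
    if len(np.unique(idx)) != target:  # pragma: no cover - guarded by n >= target
        raise ValueError("equidistant downsampling produced duplicate indices")
    return idx


def equidistant_downsample(
    video_frames_per_view: Mapping[str, Sequence[np.ndarray]],
    target_per_view: int = 50,
) -> FrameSet:
    """Select ``target_per_view`` evenly spaced frames from each view's video.

    Sharpness is computed here once per retained frame, so downstream stages
    never touch the full video again.
    """
    frames = []
    for view_id in sorted(video_frames_per_view):
        video = video_frames_per_view[view_id]
        idx = _equidistant_indices(len(video), target_per_view)
        for i in idx:
            img = np.asarray(video[i], dtype=float)
            frames.append(
                Frame(
                    pixels=img,
                    view_id=view_id,
                    source_index=int(i),
                    sharpness=laplacian_variance(img),
                )
            )
    return FrameSet(tuple(frames))


def eliminate_blurry(
    fs: FrameSet,
    rel_threshold: float = 0.2,
    max_removed: int = 10,
) -> FrameSet:
    """Drop frames sharper-than-threshold rule: keep sharpness >= rel_threshold * mean.

    The mean is computed over all frames of both views jointly, in a single
    pass. If more than ``max_removed`` frames fall below the threshold the
    capture is rejected outright (re-acquisition required).
    """
    if len(fs) == 0:
        raise ValueError("empty frame set")
    scores = np.array([f.sharpness for f in fs.frames])
    threshold = rel_threshold * scores.mean()
    keep = [f for f in fs.frames if f.sharpness >= threshold]
    removed = len(fs) - len(keep)
    if removed > max_removed:
        raise QualityGateError(
            f"{removed} frames below {rel_threshold:.0%} of mean sharpness "
            f"(limit {max_removed}); capture quality not up to standard, "
            "repeat image acquisition"
        )
    if not keep:
        raise ValueError("all frames rejected as blurry")
    return FrameSet(tuple(keep))


def select_keyframes(fs: FrameSet, per_view: int = 45, seed: int = 0) -> FrameSet:
    """Seeded uniform subselection of ``per_view`` frames per view.

    Output is sorted by (view_id, source_index) so downstream stages see a
    deterministic ordering.
    """
    rng = np.random.default_rng(seed)
    selected = []
    for view_id in sorted({f.view_id for f in fs.frames}):
        view_frames = fs.view(view_id)
        if len(view_frames) < per_view:
            raise ValueError(
                f"view {view_id!r} has {len(view_frames)} frames, need {per_view}"
            )
        chosen = rng.choice(len(view_frames), size=per_view, replace=False)
        selected.extend(view_frames[i] for i in chosen)
    selected.sort(key=lambda f: (f.view_id, f.source_index))
    return FrameSet(tuple(selected))


def extract_keyframes(
    video_frames_per_view: Mapping[str, Sequence[np.ndarray]],
    target_per_view: int = 50,
    per_view: int = 45,
    rel_threshold: float = 0.2,
    max_removed: int = 10,
    seed: int = 0,
) -> FrameSet:
    """Full keyframe pipeline: downsample -> blur rejection -> subselection."""
    fs = equidistant_downsample(video_frames_per_view, target_per_view)
    fs = eliminate_blurry(fs, rel_threshold=rel_threshold, max_removed=max_removed)
    return select_keyframes(fs, per_view=per_view, seed=seed)
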