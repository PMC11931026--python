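"""Image-quality metrics (MSE, PSNR) and phenotype accuracy summaries.

PSNR = 10 log10(MAX^2 / MSE) in decibels, with MAX = 1.0 for float images or
255 after 8-bit export (both supported; the convention is reported alongside
the value). Phenotype accuracy over a set of plants is summarized by the mean
absolute error and the coefficient of determination R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = ["mse", "psnr", "phenotype_stats", "MetricReport"]


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared pixel difference, averaged over all pixels and channels."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def psnr(a: np.ndarray, b: np.ndarray, max_i: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; identical images give +inf."""
    m = mse(a, b)
    if m == 0:
        return float("inf")
    return float(10.0 * np.log10(max_i**2 / m))


def phenotype_stats(estimated, truth) -> tuple[float, float]:
    """(MAE, R^2) between estimated and true phenotype values.

    R^2 = 1 - SS_res / SS_tot; a truth vector with zero variance has no
    defined R^2 and raises.
    """
    e = np.asarray(estimated, dtype=float).reshape(-1)
    t = np.asarray(truth, dtype=float).reshape(-1)
    if len(e) != len(t) or len(t) < 2:
        raise ValueError("need equal-length sequences of at least 2 values")
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("truth values have zero variance; R^2 undefined")
    mae = float(np.mean(np.abs(e - t)))
    r2 = 1.0 - float(np.sum((e - t) ** 2)) / ss_tot
    return mae, r2


@dataclass
class MetricReport:
    """Per-image and aggregate image-quality numbers for a validation run."""

    max_i: float = 1.0
    per_image_mse: list = dc_field(default_factory=list)
    per_image_psnr: list = dc_field(default_factory=list)

    def add(self, real: np.ndarray, synthesized: np.ndarray) -> float:
        m = mse(real, synthesized)
        p = psnr(real, synthesized, self.max_i)
        self.per_image_mse.append(m)
        self.per_image_psnr.append(p)
        return p

    @property
    def mean_psnr(self) -> float:
        return float(np.mean(self.per_image_psnr))

    def to_dict(self) -> dict:
        return {
            "max_i": self.max_i,
            "per_image_mse": list(map(float, self.per_image_mse)),
            "per_image_psnr": list(map(float, self.per_image_psnr)),
            "mean_psnr": self.mean_psnr,
        }
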