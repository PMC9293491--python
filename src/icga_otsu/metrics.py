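"""Segmentation and image-quality metrics: MSE, SSIM, shape error, Dice.

MSE and SSIM compare intensity images (e.g. an angiography frame before
and after processing); shape error and Dice compare binary masks against
a ground truth.

Shape error is defined here as the symmetric-difference area between the
predicted and true masks normalized by the true foreground area,

    SE = |pred XOR truth| / |truth|,

a definitional choice of this package: zero iff the masks agree, 1 when
the prediction is empty, 2 for a disjoint equal-area prediction.  It is
deliberately asymmetric (normalization by the truth).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .image import ImageGrid, SegmentationMask

__all__ = [
    "MetricReport",
    "mse",
    "ssim",
    "shape_error",
    "dice",
    "evaluate_images",
    "evaluate_masks",
]


@dataclass(frozen=True)
class MetricReport:
    """Bundle of metric values; fields not computed are None."""

    mse: float | None = None
    ssim: float | None = None
    se: float | None = None
    dice: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


def _pixel_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    pa = a.pixels if isinstance(a, ImageGrid) else np.asarray(a)
    pb = b.pixels if isinstance(b, ImageGrid) else np.asarray(b)
    if pa.shape != pb.shape:
        raise ValueError(f"dimension mismatch: {pa.shape} vs {pb.shape}")
    return pa.astype(np.float64), pb.astype(np.float64)


def mse(a, b) -> float:
    """Mean squared intensity difference (symmetric in its arguments)."""
    pa, pb = _pixel_pair(a, b)
    return float(np.mean((pa - pb) ** 2))


def ssim(
    a,
    b,
    k1: float = 0.01,
    k2: float = 0.03,
    data_range: float | None = None,
    windowed: bool = False,
) -> float:
    """Structural similarity between two images.

    By default a single global window is used: luminance, contrast and
    structure terms are computed from whole-image means, population
    variances and covariance, with stabilizers ``C1 = (k1 L)^2`` and
    ``C2 = (k2 L)^2`` for dynamic range ``L`` (``2**bit_depth - 1`` when
    the inputs carry a bit depth).  The global form is deterministic and
    parameter-free beyond the conventional ``k1 = 0.01``, ``k2 = 0.03``.

    ``windowed=True`` delegates to scikit-image's sliding-window mean
    SSIM instead.
    """
    pa, pb = _pixel_pair(a, b)
    if data_range is None:
        if isinstance(a, ImageGrid):
            data_range = float(a.max_value)
        else:
            data_range = 255.0
    if data_range <= 0:
        raise ValueError("data_range (dynamic range L) must be positive")
    if windowed:
        from skimage.metrics import structural_similarity

        return float(structural_similarity(pa, pb, data_range=data_range))
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu_a, mu_b = pa.mean(), pb.mean()
    var_a, var_b = pa.var(), pb.var()
    cov = float(np.mean((pa - mu_a) * (pb - mu_b)))
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    return float(num / den)


def _label_pair(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    lp = pred.labels if isinstance(pred, SegmentationMask) else np.asarray(pred, bool)
    lt = truth.labels if isinstance(truth, SegmentationMask) else np.asarray(truth, bool)
    if lp.shape != lt.shape:
        raise ValueError(f"dimension mismatch: {lp.shape} vs {lt.shape}")
    return lp, lt


def shape_error(pred, truth) -> float:
    """Symmetric-difference area over ground-truth area; 0 iff identical."""
    lp, lt = _label_pair(pred, truth)
    truth_area = int(lt.sum())
    if truth_area == 0:
        raise ValueError("ground-truth mask is empty; shape error undefined")
    return float(np.sum(lp ^ lt) / truth_area)


def dice(pred, truth) -> float:
    """Dice overlap 2|P n T| / (|P| + |T|) in [0, 1]."""
    lp, lt = _label_pair(pred, truth)
    denom = int(lp.sum()) + int(lt.sum())
    if denom == 0:
        raise ValueError("both masks empty; Dice undefined")
    return float(2.0 * np.sum(lp & lt) / denom)


def evaluate_images(a, b) -> MetricReport:
    """MSE and global SSIM for an intensity-image pair."""
    return MetricReport(mse=mse(a, b), ssim=ssim(a, b))


def evaluate_masks(pred, truth) -> MetricReport:
    """Label-space MSE, shape error and Dice for a mask pair."""
    lp, lt = _label_pair(pred, truth)
    return MetricReport(
        mse=float(np.mean((lp.astype(float) - lt.astype(float)) ** 2)),
        se=shape_error(lp, lt),
        dice=dice(lp, lt),
    )
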