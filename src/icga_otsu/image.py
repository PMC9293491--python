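"""Image I/O, histogram extraction, and threshold application.

Carries raster frames (8- or 16-bit single-channel PNG/TIFF, as exported
by angiography workstations) into the 1-based histogram convention of
:mod:`icga_otsu.otsu` and back out as binary masks.  An intensity ``v``
maps to gray level ``i = v + 1`` so ``K = 2**bit_depth``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .otsu import GrayHistogram, ThresholdResult, select_threshold

__all__ = [
    "ImageGrid",
    "SegmentationMask",
    "load_image",
    "save_mask",
    "load_mask",
    "image_histogram",
    "preprocess",
    "segment",
    "threshold_cut",
]

# Rec. 601 luma weights for RGB-encoded grayscale exports
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ImageGrid:
    """A 2-D single-channel raster with explicit bit depth (8 or 16)."""

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("image must be a non-empty 2-D array")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"unsupported bit depth {self.bit_depth}")
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        limit = 2**self.bit_depth - 1
        if np.issubdtype(px.dtype, np.floating):
            raise ValueError("image pixels must be integer-typed")
        if px.min() < 0 or px.max() > limit:
            raise ValueError(f"pixel values outside [0, {limit}]")
        object.__setattr__(self, "pixels", px.astype(dtype))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class SegmentationMask:
    """Binary foreground labeling of an image.

    ``polarity`` records which intensity side was mapped to foreground:
    ``"bright_foreground"`` (fluorescing vessels, the default downstream)
    or ``"dark_foreground"``.
    """

    labels: np.ndarray
    polarity: str = "bright_foreground"

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if labels.dtype != bool:
            uniq = np.unique(labels)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask labels must be binary")
            labels = labels.astype(bool)
        if self.polarity not in ("bright_foreground", "dark_foreground"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        object.__setattr__(self, "labels", labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def area(self) -> int:
        return int(self.labels.sum())


def load_image(path: str | Path) -> ImageGrid:
    """Read a PNG/TIFF frame as a grayscale :class:`ImageGrid`.

    RGB(A) inputs are collapsed with the Rec. 601 luma weights, which keeps
    results bit-stable for grayscale data stored in color channels.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        rgb = arr[..., :3].astype(np.float64)
        arr = np.floor(rgb @ _LUMA + 0.5)
    if arr.dtype == np.uint16:
        return ImageGrid(arr.astype(np.uint16), bit_depth=16)
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.clip(arr, 0, 255)
    return ImageGrid(arr.astype(np.uint8), bit_depth=8)


def save_mask(mask: SegmentationMask, path: str | Path) -> None:
    """Write a mask as 8-bit PNG with foreground = 255 (lossless)."""
    iio.imwrite(Path(path), mask.labels.astype(np.uint8) * 255)


def load_mask(path: str | Path, polarity: str = "bright_foreground") -> SegmentationMask:
    """Read a 0/255 (or 0/1) PNG mask back to binary labels."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return SegmentationMask(arr > 0, polarity=polarity)


def image_histogram(img: ImageGrid) -> GrayHistogram:
    """Per-level pixel counts; level ``i`` counts pixels of intensity ``i-1``."""
    k = 2**img.bit_depth
    counts = np.bincount(img.pixels.ravel(), minlength=k)
    return GrayHistogram(counts)


def preprocess(img: ImageGrid, smooth_sigma: float | None = None) -> ImageGrid:
    """Optional Gaussian smoothing; identity when no sigma is given.

    No smoothing is applied by default anywhere in the pipeline: silent
    preprocessing would change thresholds.
    """
    if smooth_sigma is None:
        return img
    if smooth_sigma <= 0:
        raise ValueError("smoothing sigma must be positive")
    blurred = ndimage.gaussian_filter(img.pixels.astype(np.float64), smooth_sigma)
    out = np.clip(np.floor(blurred + 0.5), 0, img.max_value)
    return ImageGrid(out.astype(np.uint16).astype(img.pixels.dtype), img.bit_depth)


def threshold_cut(result: ThresholdResult) -> int:
    """Integer level cut for a (possibly fractional) selected threshold.

    Tie averaging can make ``t_star`` fractional; pixels at levels up to
    ``floor(t_star + 0.5)`` (round half up) join the low class.
    """
    return int(np.floor(result.t_star + 0.5))


def segment(
    img: ImageGrid, polarity: str = "bright_foreground"
) -> tuple[SegmentationMask, ThresholdResult]:
    """Threshold an image by Otsu's method and label the foreground.

    The low class holds levels ``1..threshold_cut``; under the default
    ``bright_foreground`` polarity the high class becomes the foreground
    (ICG fluorescence renders perfused vessels bright).  Deterministic:
    the same image always yields the same threshold and mask.
    """
    result = select_threshold(image_histogram(img))
    cut = threshold_cut(result)
    low = img.pixels.astype(np.int64) + 1 <= cut
    fg = low if polarity == "dark_foreground" else ~low
    return SegmentationMask(fg, polarity=polarity), result
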