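"""Synthetic ICGA-like phantoms: a bright vessel with a saccular bulge.

The generator emulates the appearance of an indocyanine-green
fluorescence angiography field — a bright, roughly tubular parent vessel
crossing a dark background, bearing a single saccular aneurysm — without
simulating optics or hemodynamics.  A smooth random-walk centerline of
fixed caliber is rasterized, a disc bulge tangent to the centerline is
added, the two-tone image is blurred (point-spread proxy) and corrupted
with additive Gaussian noise, then clipped to the bit depth.  The ground
truth is the pre-blur geometry: blur models the instrument, not the
anatomy, so metrics score anatomy recovery.

Aneurysm size classes follow the conventional clinical cut-points:
small < 5 mm, medium 5-10 mm, large 10-25 mm, giant > 25 mm (capped at
35 mm here; small floored at 1.5 mm).  Every draw is determined by the
spec's seed, so a scene is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np
from scipy import ndimage

from .image import ImageGrid, SegmentationMask

__all__ = [
    "ANEURYSM_CLASSES",
    "PhantomSpec",
    "PhantomScene",
    "sample_aneurysm_diameter",
    "generate_phantom",
]

# diameter bounds in mm per clinical size class (lower inclusive)
ANEURYSM_CLASSES: dict[str, tuple[float, float]] = {
    "small": (1.5, 5.0),
    "medium": (5.0, 10.0),
    "large": (10.0, 25.0),
    "giant": (25.0, 35.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic angiography scene.

    Defaults put a 3 mm-caliber parent vessel on a 512x512 field at
    10 px/mm with background mean 40, vessel mean 180, PSF blur sigma 1 px
    and additive noise sigma 10 — a well-separated but noisy bimodal
    image typical of a usable ICGA frame.
    """

    width: int = 512
    height: int = 512
    pixels_per_mm: float = 10.0
    vessel_width_mm: float = 3.0
    aneurysm_class: str = "medium"
    aneurysm_diameter_mm: float | None = None  # drawn within class bounds if None
    bg_mean: float = 40.0
    fg_mean: float = 180.0
    noise_sigma: float = 10.0
    blur_sigma: float = 1.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.aneurysm_class not in ANEURYSM_CLASSES:
            raise ValueError(f"unknown aneurysm class {self.aneurysm_class!r}")
        if self.fg_mean <= self.bg_mean:
            raise ValueError("foreground mean must exceed background mean")
        if self.noise_sigma < 0 or self.blur_sigma < 0:
            raise ValueError("noise/blur sigmas must be non-negative")
        if min(self.width, self.height) < 16:
            raise ValueError("image too small for a phantom")
        if self.aneurysm_diameter_mm is not None:
            lo, hi = ANEURYSM_CLASSES[self.aneurysm_class]
            if not lo <= self.aneurysm_diameter_mm <= hi:
                raise ValueError(
                    f"diameter {self.aneurysm_diameter_mm} mm outside "
                    f"{self.aneurysm_class} bounds [{lo}, {hi}] mm"
                )

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PhantomScene:
    """A rendered phantom: image, ground truth and the generating spec."""

    image: ImageGrid
    truth: SegmentationMask
    spec: PhantomSpec  # with the drawn diameter filled in
    vessel_path: np.ndarray  # (n, 2) centerline points, (row, col)
    aneurysm_center: tuple[float, float]


def sample_aneurysm_diameter(cls: str, rng: np.random.Generator) -> float:
    """Uniform diameter draw within the class bounds, in mm."""
    lo, hi = ANEURYSM_CLASSES[cls]
    return float(rng.uniform(lo, hi))


def _centerline(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth random-walk polyline crossing the field left to right."""
    h, w = spec.height, spec.width
    step = 2.0
    n = int(np.ceil(w / step)) + 2
    heading = rng.uniform(-0.15, 0.15)
    turns = rng.normal(0.0, 0.06, size=n)
    # moving-average smoothing keeps curvature gentle (vessel-like)
    kernel = np.ones(7) / 7.0
    turns = np.convolve(turns, kernel, mode="same")
    row = rng.uniform(0.35 * h, 0.65 * h)
    col = 0.0
    pts = [(row, col)]
    for d_heading in turns:
        heading = float(np.clip(heading + d_heading, -0.9, 0.9))
        row += step * np.sin(heading)
        col += step * np.cos(heading)
        row = float(np.clip(row, 0.1 * h, 0.9 * h))
        pts.append((row, col))
        if col > w - 1:
            break
    return np.asarray(pts)


def _rasterize_tube(path: np.ndarray, radius_px: float, shape) -> np.ndarray:
    """Pixels within radius_px of the densely sampled polyline."""
    # resample at sub-pixel spacing so the distance transform sees a curve
    seg = np.diff(path, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
    dense_s = np.arange(0.0, arclen[-1], 0.5)
    rows = np.interp(dense_s, arclen, path[:, 0])
    cols = np.interp(dense_s, arclen, path[:, 1])
    grid = np.ones(shape, dtype=bool)
    rr = np.clip(np.round(rows).astype(int), 0, shape[0] - 1)
    cc = np.clip(np.round(cols).astype(int), 0, shape[1] - 1)
    grid[rr, cc] = False
    dist = ndimage.distance_transform_edt(grid)
    return dist <= radius_px


def generate_phantom(spec: PhantomSpec) -> PhantomScene:
    """Render a seeded phantom scene with its ground-truth mask.

    Raises ``ValueError`` when the (possibly drawn) aneurysm cannot fit in
    the field at the requested scale.
    """
    rng = np.random.default_rng(spec.seed)
    diameter_mm = spec.aneurysm_diameter_mm
    if diameter_mm is None:
        diameter_mm = sample_aneurysm_diameter(spec.aneurysm_class, rng)
    spec = replace(spec, aneurysm_diameter_mm=diameter_mm)

    shape = (spec.height, spec.width)
    an_radius = 0.5 * diameter_mm * spec.pixels_per_mm
    vessel_radius = 0.5 * spec.vessel_width_mm * spec.pixels_per_mm
    if 2 * an_radius >= min(spec.width, spec.height) * 0.8:
        raise ValueError(
            f"aneurysm of {diameter_mm:.1f} mm does not fit a "
            f"{spec.width}x{spec.height} field at {spec.pixels_per_mm} px/mm"
        )

    path = _centerline(spec, rng)
    vessel = _rasterize_tube(path, vessel_radius, shape)

    # saccular bulge: disc tangent to the centerline, offset perpendicular,
    # anchored at a path point far enough from the border to fit
    margin = an_radius + 2.0
    interior = np.flatnonzero(
        (path[:, 0] > margin)
        & (path[:, 0] < spec.height - margin)
        & (path[:, 1] > margin)
        & (path[:, 1] < spec.width - margin)
    )
    if interior.size == 0:
        raise ValueError("no anchor point leaves the aneurysm inside the field")
    idx = int(rng.choice(interior[interior > 0]))
    anchor = path[idx]
    tangent = path[min(idx + 1, len(path) - 1)] - path[idx - 1]
    tangent = tangent / max(np.hypot(*tangent), 1e-9)
    normal = np.array([-tangent[1], tangent[0]]) * rng.choice([-1.0, 1.0])
    center = anchor + normal * an_radius  # tangent: anchor lies on the rim
    rows, cols = np.ogrid[: spec.height, : spec.width]
    disc = (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= an_radius**2

    truth = vessel | disc
    img = np.where(truth, spec.fg_mean, spec.bg_mean).astype(np.float64)
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=shape)
    limit = 2**spec.bit_depth - 1
    img = np.clip(np.floor(img + 0.5), 0, limit)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    return PhantomScene(
        image=ImageGrid(img.astype(dtype), bit_depth=spec.bit_depth),
        truth=SegmentationMask(truth, polarity="bright_foreground"),
        spec=spec,
        vessel_path=path,
        aneurysm_center=(float(center[0]), float(center[1])),
    )
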