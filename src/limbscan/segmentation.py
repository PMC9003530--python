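"""Depth/color segmentation of the scan target.

The chain isolates the limb (or phantom) from a green-sheet backdrop in an
RGB-D frame:

1. **depth cut** — drop every pixel farther than ``depth_max_mm`` (default
   500 mm), removing the background behind the working volume;
2. **color removal** — drop pixels whose HSV color falls in the configured
   green range (the sheet covering the table);
3. **Otsu binarisation + largest region** — threshold the remaining
   grayscale support with Otsu's method and keep the largest 8-connected
   component, on the assumption that the target is the biggest object left
   in the scene;
4. **median smoothing** — iterated binary median filter (default 15×15,
   10 passes) to smooth the region boundary;
5. **erosion** — iterated morphological erosion (default 3×3, 10 passes) to
   slim the region and shed outliers that survived the depth and color cuts;
6. **masking** — bit-wise application of the final mask to the color raster.

Masks are boolean H×W arrays.  All stages are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv

from .errors import (
    DegenerateInputError,
    EmptySegmentationError,
    InvalidArgumentError,
)
from .geometry import RGBDFrame

__all__ = [
    "SegmentationConfig",
    "depth_threshold",
    "hsv_color_filter",
    "otsu_threshold",
    "largest_region",
    "median_filter",
    "erode",
    "segment",
]

#: Default HSV interval treated as "sheet green": hue in degrees [0, 360),
#: saturation and value in [0, 1].
DEFAULT_HSV_LOWER = (70.0, 0.25, 0.2)
DEFAULT_HSV_UPPER = (170.0, 1.0, 1.0)


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the segmentation chain."""

    depth_max_mm: float = 500.0
    hsv_lower: tuple[float, float, float] = DEFAULT_HSV_LOWER
    hsv_upper: tuple[float, float, float] = DEFAULT_HSV_UPPER
    median_size: int = 15
    median_iters: int = 10
    erosion_size: int = 3
    erosion_iters: int = 10

    def __post_init__(self):
        if self.depth_max_mm <= 0:
            raise InvalidArgumentError("depth_max_mm must be positive")
        for name in ("median_size", "erosion_size"):
            s = getattr(self, name)
            if s < 1 or s % 2 == 0:
                raise InvalidArgumentError(f"{name} must be odd and ≥ 1")
        if self.median_iters < 0 or self.erosion_iters < 0:
            raise InvalidArgumentError("iteration counts must be ≥ 0")

    def to_dict(self) -> dict:
        return {
            "depth_max_mm": self.depth_max_mm,
            "hsv_lower": list(self.hsv_lower),
            "hsv_upper": list(self.hsv_upper),
            "median_size": self.median_size,
            "median_iters": self.median_iters,
            "erosion_size": self.erosion_size,
            "erosion_iters": self.erosion_iters,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SegmentationConfig":
        d = dict(d)
        for key in ("hsv_lower", "hsv_upper"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        return cls(**d)

    def scaled_to(self, width_px: int, reference_width_px: int = 1280
                  ) -> "SegmentationConfig":
        """Rescale the pixel-sized filters for a different raster width.

        The defaults are tuned for 1280-px-wide frames; at a reduced render
        size the same pixel windows would strip a proportionally much wider
        metric rim, so window sizes and the erosion depth shrink with the
        raster.
        """
        f = width_px / reference_width_px

        def odd(x: float, lo: int = 3) -> int:
            return max(lo, int(round((x - 1) / 2)) * 2 + 1)

        return SegmentationConfig(
            depth_max_mm=self.depth_max_mm,
            hsv_lower=self.hsv_lower, hsv_upper=self.hsv_upper,
            median_size=odd(self.median_size * f),
            median_iters=self.median_iters,
            erosion_size=self.erosion_size,
            erosion_iters=max(1, round(self.erosion_iters * f)),
        )


def depth_threshold(frame: RGBDFrame, depth_max_mm: float = 500.0) -> np.ndarray:
    """Mask of pixels with valid depth at or inside ``depth_max_mm``.

    True where 0 < depth ≤ depth_max_mm; invalid (zero) depth is excluded.
    """
    depth = frame.depth_mm
    return (depth > 0) & (depth <= depth_max_mm)


def hsv_color_filter(color: np.ndarray,
                     hsv_lower=DEFAULT_HSV_LOWER,
                     hsv_upper=DEFAULT_HSV_UPPER) -> np.ndarray:
    """Mask of pixels OUTSIDE an HSV interval (the backdrop color).

    Hue is in degrees [0, 360) and may wrap (lower hue > upper hue selects
    the interval through 0°); saturation and value are in [0, 1].  Pixels
    whose HSV falls inside the interval — the sheet — come out False.
    """
    lo = np.asarray(hsv_lower, dtype=np.float64)
    hi = np.asarray(hsv_upper, dtype=np.float64)
    if lo.shape != (3,) or hi.shape != (3,):
        raise InvalidArgumentError("HSV bounds must be 3-vectors")
    if np.any(lo[1:] > hi[1:]):
        raise InvalidArgumentError("saturation/value lower bound exceeds upper")
    hsv = rgb2hsv(np.asarray(color, dtype=np.float64) / 255.0)
    h = hsv[..., 0] * 360.0
    if lo[0] <= hi[0]:
        in_hue = (h >= lo[0]) & (h <= hi[0])
    else:  # wrap-around through 0°
        in_hue = (h >= lo[0]) | (h <= hi[0])
    in_range = (
        in_hue
        & (hsv[..., 1] >= lo[1]) & (hsv[..., 1] <= hi[1])
        & (hsv[..., 2] >= lo[2]) & (hsv[..., 2] <= hi[2])
    )
    return ~in_range


def otsu_threshold(gray: np.ndarray) -> int:
    """Otsu's threshold over a 256-bin histogram.

    Returns the intensity th in [0, 255] minimising the within-class
    variance ω₀σ₀² + ω₁σ₁² of the two classes {≤ th} and {> th}
    (equivalently maximising the between-class variance).  Binarisation is
    ``value > th``.  Ties go to the smallest threshold.
    """
    g = np.asarray(gray)
    if np.issubdtype(g.dtype, np.floating):
        g = np.clip(np.rint(g), 0, 255).astype(np.uint8)
    if g.min() == g.max():
        raise DegenerateInputError("constant raster has no Otsu threshold")
    hist = np.bincount(g.ravel().astype(np.int64), minlength=256).astype(np.float64)
    total = hist.sum()
    omega0 = np.cumsum(hist) / total            # P(class ≤ th), th = 0..255
    mu_cum = np.cumsum(hist * np.arange(256)) / total
    mu_total = mu_cum[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_total * omega0 - mu_cum) ** 2 / (omega0 * omega1)
    between[~np.isfinite(between)] = -np.inf
    return int(np.argmax(between[:-1]))  # th = 255 would leave class 1 empty


def largest_region(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected component of a binary mask.

    Ties between equal-sized components are broken deterministically in
    favour of the component whose first pixel comes earliest in row-major
    scan order.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptySegmentationError("largest_region", "mask is entirely false")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best_size = counts.max()
    candidates = np.flatnonzero(counts == best_size)
    if len(candidates) == 1:
        best = candidates[0]
    else:
        # scipy labels components in scan order, so the smallest label among
        # the tied components is the one first reached in row-major order.
        best = candidates.min()
    return labels == best


def _box_count(mask: np.ndarray, size: int) -> np.ndarray:
    """Count of true pixels in each size×size window, reflect padding."""
    counts = ndimage.uniform_filter(mask.astype(np.float64), size=size,
                                    mode="reflect") * (size * size)
    return np.rint(counts).astype(np.int64)


def median_filter(mask: np.ndarray, size: int = 15, iterations: int = 10
                  ) -> np.ndarray:
    """Iterated binary median filter with reflect padding at borders.

    For a binary raster the window median is 1 exactly when more than half
    the size² window pixels are 1, so each pass reduces to a box count and
    a majority test (size odd ⇒ the window count is odd ⇒ no ties).
    """
    if size < 1 or size % 2 == 0:
        raise InvalidArgumentError("median window size must be odd")
    out = np.asarray(mask, dtype=bool)
    half = (size * size) // 2
    for _ in range(iterations):
        out = _box_count(out, size) > half
    return out


def erode(mask: np.ndarray, size: int = 3, iterations: int = 10) -> np.ndarray:
    """Iterated binary erosion with a size×size square element.

    A pixel survives a pass only if its whole window is true; pixels outside
    the image count as false, so each pass also strips the image border.
    """
    if size < 1 or size % 2 == 0:
        raise InvalidArgumentError("erosion element size must be odd")
    mask = np.asarray(mask, dtype=bool)
    if iterations == 0:
        return mask.copy()
    return ndimage.binary_erosion(
        mask, structure=np.ones((size, size), dtype=bool),
        iterations=iterations, border_value=0,
    )


_LUMA = np.array([0.2125, 0.7154, 0.0721])  # Rec. 709 grayscale weights


def segment(frame: RGBDFrame, config: SegmentationConfig = SegmentationConfig(),
             return_stages: bool = False):
    """Run the full segmentation chain on one RGB-D frame.

    Returns ``(mask, masked_color)`` — the final boolean mask and the color
    raster with everything outside the mask zeroed.  With
    ``return_stages=True`` a dict of the intermediate masks is returned as a
    third element for debugging.  Raises :class:`EmptySegmentationError`
    naming the stage if any stage empties the mask.
    """
    stages: dict[str, np.ndarray] = {}

    depth_mask = depth_threshold(frame, config.depth_max_mm)
    stages["depth"] = depth_mask
    if not depth_mask.any():
        raise EmptySegmentationError("depth")

    color_mask = hsv_color_filter(frame.color, config.hsv_lower, config.hsv_upper)
    support = depth_mask & color_mask
    stages["color"] = support
    if not support.any():
        raise EmptySegmentationError("color")

    # Otsu on the grayscale of the color raster restricted to the support;
    # outside-support pixels are zeroed so they fall in the dark class.
    gray = np.zeros(support.shape, dtype=np.float64)
    gray[support] = (frame.color[support].astype(np.float64) @ _LUMA)
    try:
        th = otsu_threshold(gray)
        binary = (gray > th) & support
    except DegenerateInputError:
        # uniform brightness over the support: the support itself is the
        # binary image
        binary = support.copy()
    if not binary.any():
        # Otsu put the whole support in the dark class; keep the support.
        binary = support.copy()
    stages["binary"] = binary

    region = largest_region(binary)
    stages["region"] = region

    smoothed = median_filter(region, config.median_size, config.median_iters)
    # median may grow the region at concavities; keep it inside the support
    smoothed &= support
    stages["median"] = smoothed
    if not smoothed.any():
        raise EmptySegmentationError("median")

    final = erode(smoothed, config.erosion_size, config.erosion_iters)
    stages["erosion"] = final
    if not final.any():
        raise EmptySegmentationError("erosion")

    masked = frame.color.copy()
    masked[~final] = 0
    if return_stages:
        return final, masked, stages
    return final, masked
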