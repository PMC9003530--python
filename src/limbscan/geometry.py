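"""Pinhole camera model, rig design equations, and RGB-D ↔ point-cloud mapping.

The design equations answer the questions that fix the physical rig: given a
camera's field of view and a standoff distance, what metric area does one
image cover and at what resolution (mm per pixel)?  Given the circumference
of a limb, what frame radius keeps the cameras inside the sensor's ideal
depth range?  All lengths are millimetres, all image coordinates are 0-based
pixels with (u, v) = (column, row) and the origin at the top-left.

The camera frame is right-handed with +z along the optical axis into the
scene, +x right and +y down.  Depth images store millimetres in 16-bit
integers (``depth_scale`` millimetres per stored unit, default 1); a stored
depth of 0 marks an invalid pixel and is excluded from deprojection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import BehindCameraError, InvalidArgumentError

__all__ = [
    "CameraIntrinsics",
    "RGBDFrame",
    "PointCloud",
    "focal_length",
    "fov_extent",
    "resolution",
    "truncate_decimals",
    "circumference_to_radius",
    "standoff_distance",
    "deproject",
    "project",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole parameters mapping pixels to metric rays.

    Parameters
    ----------
    width_px, height_px
        Image size in pixels.
    fx, fy
        Focal lengths in pixels.
    cx, cy
        Principal point in pixels (0-based, inside the image).
    depth_scale
        Millimetres per stored depth unit (1 for depth images already in mm).
    """

    width_px: int
    height_px: int
    fx: float
    fy: float
    cx: float
    cy: float
    depth_scale: float = 1.0

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise InvalidArgumentError("image size must be positive")
        if self.fx <= 0 or self.fy <= 0:
            raise InvalidArgumentError("focal lengths must be positive")
        if self.depth_scale <= 0:
            raise InvalidArgumentError("depth_scale must be positive")
        if not (0 <= self.cx < self.width_px and 0 <= self.cy < self.height_px):
            raise InvalidArgumentError("principal point must lie inside the image")

    def to_dict(self) -> dict:
        return {
            "width": self.width_px,
            "height": self.height_px,
            "fx": self.fx,
            "fy": self.fy,
            "cx": self.cx,
            "cy": self.cy,
            "depth_scale": self.depth_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraIntrinsics":
        return cls(
            width_px=int(d["width"]),
            height_px=int(d["height"]),
            fx=float(d["fx"]),
            fy=float(d["fy"]),
            cx=float(d["cx"]),
            cy=float(d["cy"]),
            depth_scale=float(d.get("depth_scale", 1.0)),
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load_json(cls, path: str | Path) -> "CameraIntrinsics":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class RGBDFrame:
    """A color raster with its aligned depth raster.

    ``color`` is H×W×3 uint8; ``depth`` is H×W in millimetres (float or
    uint16) with 0 marking invalid pixels.  Color and depth are assumed
    pre-aligned pixel-for-pixel, as delivered by RGB-D sensors that align
    the streams in firmware.
    """

    color: np.ndarray
    depth: np.ndarray
    intrinsics: CameraIntrinsics

    def __post_init__(self):
        self.color = np.asarray(self.color)
        self.depth = np.asarray(self.depth)
        if self.color.ndim != 3 or self.color.shape[2] != 3:
            raise InvalidArgumentError("color must be H×W×3")
        if self.depth.shape != self.color.shape[:2]:
            raise InvalidArgumentError("color and depth shapes differ")
        h, w = self.depth.shape
        if (w, h) != (self.intrinsics.width_px, self.intrinsics.height_px):
            raise InvalidArgumentError("frame shape does not match intrinsics")
        if np.any(np.asarray(self.depth, dtype=float) < 0):
            raise InvalidArgumentError("depth values must be non-negative")

    @property
    def depth_mm(self) -> np.ndarray:
        """Depth in millimetres as float64 (0 = invalid)."""
        return self.depth.astype(np.float64) * self.intrinsics.depth_scale


@dataclass
class PointCloud:
    """3-D points in millimetres with optional per-point color and normals.

    Colors are RGB in [0, 1]; normals are unit vectors.  Attribute arrays,
    when present, have exactly one row per point.
    """

    points: np.ndarray
    colors: np.ndarray | None = None
    normals: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 3)
        if self.points.shape[1] != 3:
            raise InvalidArgumentError("points must be N×3")
        n = len(self.points)
        for name in ("colors", "normals"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=np.float64)
                if arr.shape != (n, 3):
                    raise InvalidArgumentError(f"{name} must be N×3 matching points")
                setattr(self, name, arr)
        if self.normals is not None and n:
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise InvalidArgumentError("normals must be unit length")

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# Rig design equations
# ---------------------------------------------------------------------------

def focal_length(image_extent_px: float, target_extent_mm: float,
                 distance_mm: float) -> float:
    """Focal length (px) that maps ``target_extent_mm`` at ``distance_mm``
    onto ``image_extent_px`` pixels: f = B / G · l with B the image extent,
    G the target extent and l the standoff distance."""
    if image_extent_px <= 0 or target_extent_mm <= 0 or distance_mm <= 0:
        raise InvalidArgumentError("all arguments must be positive")
    return image_extent_px / target_extent_mm * distance_mm


def fov_extent(fov_degrees: float, distance_mm: float) -> float:
    """Metric extent covered by a full field-of-view angle at a distance:
    2·tan(fov/2)·l."""
    if not 0 <= fov_degrees < 180:
        raise InvalidArgumentError("fov must be in [0, 180) degrees")
    if distance_mm < 0:
        raise InvalidArgumentError("distance must be non-negative")
    return 2.0 * math.tan(math.radians(fov_degrees) / 2.0) * distance_mm


def resolution(target_extent_mm: float, image_extent_px: float) -> float:
    """Image resolution in mm per pixel: target extent / pixel count."""
    if target_extent_mm <= 0 or image_extent_px <= 0:
        raise InvalidArgumentError("all arguments must be positive")
    return target_extent_mm / image_extent_px


def truncate_decimals(value: float, ndigits: int = 2) -> float:
    """Truncate toward zero at ``ndigits`` decimals.

    Reported design figures (e.g. the mm/px resolution) quote the leading
    decimals of the exact value rather than the nearest rounding: 0.2488
    mm/px is quoted as 0.24.
    """
    scale = 10 ** ndigits
    return math.trunc(value * scale) / scale


def circumference_to_radius(circumference_mm: float) -> tuple[float, float]:
    """Diameter and radius of a circle of the given circumference.

    Used to size the rig from a limb circumference measurement:
    d = c/π, r = d/2.
    """
    if circumference_mm <= 0:
        raise InvalidArgumentError("circumference must be positive")
    d = circumference_mm / math.pi
    return d, d / 2.0


def standoff_distance(frame_radius_mm: float, target_radius_mm: float) -> float:
    """Camera-to-surface distance: frame radius minus target radius."""
    if target_radius_mm < 0 or frame_radius_mm < target_radius_mm:
        raise InvalidArgumentError("frame radius must be ≥ target radius ≥ 0")
    return frame_radius_mm - target_radius_mm


# ---------------------------------------------------------------------------
# RGB-D ↔ point cloud
# ---------------------------------------------------------------------------

def deproject(frame: RGBDFrame, mask: np.ndarray | None = None) -> PointCloud:
    """Back-project every valid depth pixel into a 3-D point.

    A pixel (u, v) with depth z > 0 (and, if a mask is given, mask true)
    emits the point

        x = (u − cx)·z / fx,   y = (v − cy)·z / fy,   z = z,

    in the camera frame, carrying the pixel's color scaled to [0, 1].
    Pixels with z = 0 or mask false emit nothing.
    """
    K = frame.intrinsics
    depth = frame.depth_mm
    valid = depth > 0
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != depth.shape:
            raise InvalidArgumentError("mask shape does not match frame")
        valid &= mask
    v_idx, u_idx = np.nonzero(valid)
    z = depth[v_idx, u_idx]
    x = (u_idx - K.cx) * z / K.fx
    y = (v_idx - K.cy) * z / K.fy
    points = np.column_stack([x, y, z])
    colors = frame.color[v_idx, u_idx].astype(np.float64) / 255.0
    return PointCloud(points=points, colors=colors)


def project(point: np.ndarray, intrinsics: CameraIntrinsics
            ) -> tuple[float, float, float]:
    """Project a camera-frame point to pixel coordinates plus depth.

    Exact inverse of :func:`deproject` for in-bounds pixels.
    """
    x, y, z = np.asarray(point, dtype=np.float64)
    if z <= 0:
        raise BehindCameraError("point is behind the camera (z ≤ 0)")
    u = intrinsics.fx * x / z + intrinsics.cx
    v = intrinsics.fy * y / z + intrinsics.cy
    return float(u), float(v), float(z)
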