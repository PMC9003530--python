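"""File I/O: PNG rasters and PLY point clouds.

Color images are 8-bit RGB PNG; depth images are 16-bit single-channel PNG
in millimetres (0 = invalid); masks are 8-bit single-channel PNG with
255 = true.  Point clouds are binary little-endian PLY with optional
per-point normal and color properties (a compact structured-array codec —
meshes use trimesh's PLY/OBJ writers instead).
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InvalidArgumentError
from .geometry import PointCloud

__all__ = [
    "write_color_png", "read_color_png",
    "write_depth_png", "read_depth_png",
    "write_mask_png", "read_mask_png",
    "write_ply", "read_ply",
]


def write_color_png(path: str | Path, color: np.ndarray) -> None:
    color = np.asarray(color)
    if color.ndim != 3 or color.shape[2] != 3 or color.dtype != np.uint8:
        raise InvalidArgumentError("color must be H×W×3 uint8")
    iio.imwrite(Path(path), color, extension=".png")


def read_color_png(path: str | Path) -> np.ndarray:
    img = iio.imread(Path(path))
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    return np.asarray(img, dtype=np.uint8)


def write_depth_png(path: str | Path, depth_mm: np.ndarray) -> None:
    """Store a depth raster as 16-bit millimetres (rounded to nearest)."""
    depth = np.asarray(depth_mm, dtype=np.float64)
    if np.any(depth < 0) or np.any(depth > np.iinfo(np.uint16).max):
        raise InvalidArgumentError("depth out of 16-bit millimetre range")
    iio.imwrite(Path(path), np.rint(depth).astype(np.uint16), extension=".png")


def read_depth_png(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)), dtype=np.uint16)


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask, dtype=bool)
    iio.imwrite(Path(path), (mask * np.uint8(255)), extension=".png")


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


_PLY_DTYPES = {"float": "<f4", "double": "<f8", "uchar": "u1",
               "int": "<i4", "uint": "<u4", "short": "<i2", "ushort": "<u2"}


def write_ply(path: str | Path, cloud: PointCloud) -> None:
    """Write a point cloud as binary little-endian PLY (double precision
    coordinates; normals and colors included when present)."""
    fields = [("x", "<f8"), ("y", "<f8"), ("z", "<f8")]
    props = ["property double x", "property double y", "property double z"]
    if cloud.normals is not None:
        fields += [("nx", "<f8"), ("ny", "<f8"), ("nz", "<f8")]
        props += [f"property double n{c}" for c in "xyz"]
    if cloud.colors is not None:
        fields += [("red", "u1"), ("green", "u1"), ("blue", "u1")]
        props += [f"property uchar {c}" for c in ("red", "green", "blue")]
    rec = np.empty(len(cloud), dtype=fields)
    rec["x"], rec["y"], rec["z"] = cloud.points.T
    if cloud.normals is not None:
        rec["nx"], rec["ny"], rec["nz"] = cloud.normals.T
    if cloud.colors is not None:
        rgb = np.clip(np.rint(cloud.colors * 255.0), 0, 255).astype(np.uint8)
        rec["red"], rec["green"], rec["blue"] = rgb.T
    header = "\n".join(
        ["ply", "format binary_little_endian 1.0",
         f"element vertex {len(cloud)}"] + props + ["end_header", ""])
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(rec.tobytes())


def read_ply(path: str | Path) -> PointCloud:
    """Read a binary little-endian PLY vertex list written by
    :func:`write_ply` (or any single-element PLY with scalar properties)."""
    with open(path, "rb") as fh:
        line = fh.readline().strip()
        if line != b"ply":
            raise InvalidArgumentError("not a PLY file")
        n = None
        fields: list[tuple[str, str]] = []
        while True:
            line = fh.readline()
            if not line:
                raise InvalidArgumentError("truncated PLY header")
            tok = line.decode("ascii").split()
            if not tok or tok[0] == "comment":
                continue
            if tok[0] == "format" and tok[1] != "binary_little_endian":
                raise InvalidArgumentError("only binary little-endian PLY supported")
            if tok[0] == "element":
                if tok[1] != "vertex":
                    raise InvalidArgumentError("only vertex elements supported")
                n = int(tok[2])
            elif tok[0] == "property":
                if tok[1] == "list":
                    raise InvalidArgumentError("list properties not supported")
                fields.append((tok[2], _PLY_DTYPES[tok[1]]))
            elif tok[0] == "end_header":
                break
        if n is None:
            raise InvalidArgumentError("PLY has no vertex element")
        rec = np.frombuffer(fh.read(), dtype=np.dtype(fields), count=n)
    points = np.column_stack([rec[c].astype(np.float64) for c in "xyz"])
    names = {f[0] for f in fields}
    normals = colors = None
    if {"nx", "ny", "nz"} <= names:
        normals = np.column_stack([rec[f"n{c}"].astype(np.float64)
                                   for c in "xyz"])
    if {"red", "green", "blue"} <= names:
        colors = np.column_stack([rec[c].astype(np.float64) / 255.0
                                  for c in ("red", "green", "blue")])
    return PointCloud(points=points, colors=colors, normals=normals)
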