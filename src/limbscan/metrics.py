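"""Validation metrics: Dice overlap, Hausdorff distance, distance fields for
heat maps, summary statistics, and diameter-at-height measurement.

Dice measures region overlap between a computed and a reference binary
segmentation (1 = identical, 0 = disjoint); the Hausdorff distance is the
worst-case nearest-neighbour distance between two point sets (or the true
pixels of two masks), a conservative shape discrepancy.  Mask-based
distances are in pixels and convert to millimetres through the system
resolution; point- and mesh-based distances are in millimetres.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidArgumentError, OutOfRangeError, UndefinedMetricError
from .meshing import TriangleMesh

__all__ = [
    "SummaryStats",
    "dice",
    "hausdorff",
    "nearest_distances",
    "summary_stats",
    "px_to_mm",
    "cross_section_extent",
    "mesh_distances",
]

_STAT_FIELDS = ("min", "q1", "median", "mean", "q3", "max", "iqr", "rms")


@dataclass(frozen=True)
class SummaryStats:
    """One row of distribution summaries in the data's own units.

    Quartiles use linear interpolation between order statistics; ``rms`` is
    sqrt(mean(x²)) of the data values themselves.
    """

    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float
    iqr: float
    rms: float

    def to_dict(self) -> dict:
        return asdict(self)

    def round(self, ndigits: int = 2) -> "SummaryStats":
        return SummaryStats(**{k: round(v, ndigits)
                               for k, v in self.to_dict().items()})


def _as_point_set(x: np.ndarray) -> np.ndarray:
    """Interpret a 2-D boolean raster as (row, col) pixel-centre
    coordinates of its true pixels; pass point arrays through."""
    x = np.asarray(x)
    is_binary = x.dtype == bool or (np.issubdtype(x.dtype, np.integer)
                                    and x.size and x.max() <= 1 >= -x.min())
    if x.ndim == 2 and is_binary:
        return np.argwhere(x.astype(bool)).astype(np.float64)
    return np.atleast_2d(x.astype(np.float64))


def dice(A: np.ndarray, B: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A| + |B|) of two binary masks."""
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if A.shape != B.shape:
        raise InvalidArgumentError("masks must have equal shapes")
    total = int(A.sum()) + int(B.sum())
    if total == 0:
        raise UndefinedMetricError("Dice is undefined for two empty masks")
    return 2.0 * int((A & B).sum()) / total


def nearest_distances(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Distance from each point of P to its nearest point of Q.

    Both arguments may be point arrays or binary masks (true-pixel
    coordinates are used).  The per-point field drives distance heat maps;
    the maximum over both directions is the Hausdorff distance.
    """
    P, Q = _as_point_set(P), _as_point_set(Q)
    if len(Q) == 0:
        raise UndefinedMetricError("no target points to measure against")
    if len(P) == 0:
        return np.empty(0)
    d, _ = cKDTree(Q).query(P)
    return d


def hausdorff(A: np.ndarray, B: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets or masks:
    max(sup_{p∈A} inf_{q∈B} d(p,q), sup_{q∈B} inf_{p∈A} d(q,p))."""
    A, B = _as_point_set(A), _as_point_set(B)
    if len(A) == 0 or len(B) == 0:
        raise UndefinedMetricError("Hausdorff is undefined for empty sets")
    return float(max(nearest_distances(A, B).max(),
                     nearest_distances(B, A).max()))


def summary_stats(values: np.ndarray) -> SummaryStats:
    """Summary row (min, quartiles, mean, max, IQR, RMS) of a sample."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise InvalidArgumentError("summary of an empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    return SummaryStats(
        min=float(v.min()), q1=float(q1), median=float(med),
        mean=float(v.mean()), q3=float(q3), max=float(v.max()),
        iqr=float(q3 - q1), rms=float(np.sqrt(np.mean(v ** 2))),
    )


def px_to_mm(value_px: float, res_mm_per_px: float) -> float:
    """Convert a pixel measurement to millimetres through the system
    resolution (mm per pixel)."""
    if res_mm_per_px <= 0:
        raise InvalidArgumentError("resolution must be positive")
    return value_px * res_mm_per_px


def cross_section_extent(mesh: TriangleMesh, height_mm: float,
                         axis=(0.0, 0.0, 1.0),
                         direction=(1.0, 0.0, 0.0)) -> float:
    """Diameter of a mesh cross-section: slice the mesh with the plane
    normal to ``axis`` at ``height_mm`` and return the extent of the
    section outline projected on ``direction``.

    Reproduces a caliper measurement of a scanned model at a given height.
    """
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    direction = np.asarray(direction, dtype=np.float64)
    direction = direction / np.linalg.norm(direction)
    tm = mesh.as_trimesh()
    section = tm.section(plane_origin=axis * height_mm, plane_normal=axis)
    if section is None or len(section.vertices) == 0:
        raise OutOfRangeError(f"the plane at {height_mm} mm misses the mesh")
    proj = np.asarray(section.vertices) @ direction
    return float(proj.max() - proj.min())


def mesh_distances(mesh: TriangleMesh, reference: TriangleMesh,
                   n_samples: int = 100_000, seed: int = 0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric surface-to-surface distance samples between two meshes.

    Each surface is sampled densely (``n_samples`` points) and measured
    against the other's samples; returns the two directed per-point
    distance arrays (mesh→reference, reference→mesh).  Their concatenation
    feeds :func:`summary_stats`; the max over both is the sampled Hausdorff
    distance.
    """
    rng = np.random.default_rng(seed)
    a = _sample_surface(mesh, n_samples, rng)
    b = _sample_surface(reference, n_samples, rng)
    return nearest_distances(a, b), nearest_distances(b, a)


def _sample_surface(mesh: TriangleMesh, n: int, rng: np.random.Generator
                    ) -> np.ndarray:
    """Area-weighted uniform surface samples."""
    v, f = mesh.vertices, mesh.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    total = areas.sum()
    if total <= 0:
        raise InvalidArgumentError("mesh has zero surface area")
    tri = rng.choice(len(f), size=n, p=areas / total)
    r1, r2 = rng.random(n), rng.random(n)
    swap = r1 + r2 > 1
    r1[swap], r2[swap] = 1 - r1[swap], 1 - r2[swap]
    return a[tri] + r1[:, None] * (b[tri] - a[tri]) + r2[:, None] * (c[tri] - a[tri])


def write_report(path_json: str | Path, rows: dict[str, SummaryStats],
                 path_csv: str | Path | None = None) -> None:
    """Write an evaluation report: one SummaryStats row per comparison."""
    data = {name: s.to_dict() for name, s in rows.items()}
    Path(path_json).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    if path_csv is not None:
        with open(path_csv, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(("comparison",) + _STAT_FIELDS)
            for name, s in rows.items():
                d = s.to_dict()
                w.writerow([name] + [d[k] for k in _STAT_FIELDS])
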