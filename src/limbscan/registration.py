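"""Point-cloud alignment: global placement from extrinsics, voxel
downsampling, normal estimation, and point-to-plane ICP refinement.

The fusion strategy mirrors how the physical rig is used: each camera's
cloud is first placed in the reference frame with the calibrated extrinsics
(the rough, global alignment), then refined one camera at a time — in the
order the cameras sit on the frame — against the accumulated merged cloud
with the iterative-closest-point algorithm.  The point-to-plane variant is
used because the clouds come pre-aligned: it minimises

    E(T) = Σ_{(p,q) ∈ κ} ((p − T·q)·n_p)²

over rigid transforms T, where κ pairs each source point q with its nearest
target point p (within a correspondence radius) and n_p is the target
normal.  Distances along the surface normal ignore sliding within the
surface, which converges much faster than point-to-point on smooth shapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial import cKDTree

from .calibration import RigidTransform
from .errors import InvalidArgumentError, NoOverlapError
from .geometry import PointCloud

__all__ = [
    "ICPParams",
    "apply_transform",
    "voxel_downsample",
    "estimate_normals",
    "point_to_plane_objective",
    "icp_point_to_plane",
    "pairwise_register",
]


@dataclass(frozen=True)
class ICPParams:
    """ICP refinement parameters.

    ``max_correspondence_mm`` is the nearest-neighbour rejection radius;
    ``voxel_size_mm`` (default 2 mm) is the downsampling cell edge used
    when merging.
    """

    max_correspondence_mm: float = 10.0
    max_iterations: int = 50
    rel_tolerance: float = 1e-6
    voxel_size_mm: float = 2.0

    def __post_init__(self):
        if min(self.max_correspondence_mm, self.rel_tolerance,
               self.voxel_size_mm) <= 0 or self.max_iterations < 1:
            raise InvalidArgumentError("ICP parameters must be positive")


def apply_transform(cloud: PointCloud, T: RigidTransform) -> PointCloud:
    """Rigidly move a cloud: points p ↦ R·p + t, normals n ↦ R·n."""
    normals = None if cloud.normals is None else cloud.normals @ T.rotation.T
    colors = None if cloud.colors is None else cloud.colors.copy()
    return PointCloud(points=T.apply(cloud.points), colors=colors,
                      normals=normals)


def voxel_downsample(cloud: PointCloud, voxel_size_mm: float) -> PointCloud:
    """One point per occupied voxel, at the centroid of the voxel's members.

    Voxels are axis-aligned cubes of edge ``voxel_size_mm`` anchored at the
    origin.  Optional attributes are averaged per voxel; normals are
    re-normalised after averaging.
    """
    if voxel_size_mm <= 0:
        raise InvalidArgumentError("voxel size must be positive")
    if len(cloud) == 0:
        return PointCloud(points=np.empty((0, 3)))
    keys = np.floor(cloud.points / voxel_size_mm).astype(np.int64)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True,
                                   return_counts=True)

    def _mean(arr):
        out = np.zeros((len(counts), 3))
        np.add.at(out, inverse, arr)
        return out / counts[:, None]

    points = _mean(cloud.points)
    colors = None if cloud.colors is None else _mean(cloud.colors)
    normals = None
    if cloud.normals is not None:
        normals = _mean(cloud.normals)
        norms = np.linalg.norm(normals, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        normals = normals / norms
    return PointCloud(points=points, colors=colors, normals=normals)


def estimate_normals(cloud: PointCloud, k: int = 20,
                     viewpoint: np.ndarray | Sequence[float] = (0.0, 0.0, 0.0)
                     ) -> PointCloud:
    """Per-point normals from local PCA over the k nearest neighbours.

    The normal at a point is the eigenvector of the neighbourhood
    covariance with the smallest eigenvalue, oriented so that it faces the
    given viewpoint (n·(viewpoint − p) ≥ 0).
    """
    n = len(cloud)
    if n <= k or k < 3:
        raise InvalidArgumentError("need more points than neighbours, k ≥ 3")
    pts = cloud.points
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k + 1)      # first neighbour is the point itself
    neigh = pts[idx]                       # N × (k+1) × 3
    centred = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nij,nik->njk", centred, centred) / (k + 1)
    _, vecs = np.linalg.eigh(cov)          # ascending eigenvalues
    normals = vecs[:, :, 0]
    flip = np.einsum("ij,ij->i", normals,
                     np.asarray(viewpoint, dtype=np.float64) - pts) < 0
    normals[flip] *= -1.0
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(points=pts.copy(), colors=None if cloud.colors is None
                      else cloud.colors.copy(), normals=normals)


def point_to_plane_objective(source: PointCloud, target: PointCloud,
                             target_tree: cKDTree, T: RigidTransform,
                             max_corr: float) -> tuple[float, np.ndarray,
                                                       np.ndarray, np.ndarray]:
    """Evaluate E(T) and return the matched arrays for the linearised solve.

    Returns (E, moved source points, matched target points, matched target
    normals) for correspondences within ``max_corr``.
    """
    moved = T.apply(source.points)
    dist, idx = target_tree.query(moved, distance_upper_bound=max_corr)
    keep = np.isfinite(dist)
    if not keep.any():
        return np.inf, moved[:0], moved[:0], moved[:0]
    q = moved[keep]
    p = target.points[idx[keep]]
    n = target.normals[idx[keep]]
    r = np.einsum("ij,ij->i", p - q, n)
    return float(np.sum(r * r)), q, p, n


def icp_point_to_plane(source: PointCloud, target: PointCloud,
                       init: RigidTransform | None = None,
                       params: ICPParams = ICPParams()
                       ) -> tuple[RigidTransform, float]:
    """Refine the alignment of ``source`` onto ``target`` (which must carry
    normals) by point-to-plane ICP.

    Starting from ``init`` (identity if omitted), each iteration matches
    every transformed source point to its nearest target point within the
    correspondence radius, then solves the 6×6 linearised least-squares
    system for the small rotation/translation update minimising E.  Updates
    that fail to decrease E are rejected and terminate the loop, so the
    returned objective never exceeds the objective at ``init``.  Returns the
    total transform (including ``init``) and the final objective value.
    """
    if target.normals is None:
        raise InvalidArgumentError("target cloud must carry normals")
    if len(source) == 0:
        raise InvalidArgumentError("source cloud is empty")
    T = RigidTransform.identity() if init is None else init
    tree = cKDTree(target.points)
    E, q, p, n = point_to_plane_objective(source, target, tree, T,
                                          params.max_correspondence_mm)
    if not np.isfinite(E):
        raise NoOverlapError("no correspondences within the search radius")
    for _ in range(params.max_iterations):
        # Linearise about the current pose: moving point q by (ω × q + t)
        # changes the residual n·(p − q) by −n·(ω × q) − n·t.
        J = np.hstack([np.cross(q, n), n])          # M × 6
        r = np.einsum("ij,ij->i", p - q, n)         # M
        A = J.T @ J
        b = J.T @ r
        try:
            delta = cho_solve(cho_factor(A + 1e-12 * np.eye(6)), b)
        except np.linalg.LinAlgError:
            break
        omega, t = delta[:3], delta[3:]
        angle = np.linalg.norm(omega)
        R_step = _rotation_from_axis_angle(omega, angle)
        T_candidate = RigidTransform(R_step, t) @ T
        E_new, q_new, p_new, n_new = point_to_plane_objective(
            source, target, tree, T_candidate, params.max_correspondence_mm)
        if not np.isfinite(E_new):
            raise NoOverlapError("correspondences vanished during refinement")
        if E_new > E:
            break
        converged = E - E_new < params.rel_tolerance * max(E, 1e-300)
        T, E, q, p, n = T_candidate, E_new, q_new, p_new, n_new
        if converged:
            break
    return T, E


def _rotation_from_axis_angle(omega: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues' formula; exact exponential of the linearised update."""
    if angle < 1e-14:
        return np.eye(3)
    k = omega / angle
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def pairwise_register(clouds: Sequence[PointCloud],
                      extrinsics: Sequence[RigidTransform],
                      params: ICPParams = ICPParams(),
                      normals_k: int = 20) -> tuple[PointCloud,
                                                    list[RigidTransform]]:
    """Fuse per-camera clouds into one cloud in the reference frame.

    All clouds are first moved by their extrinsics (global alignment) and
    voxel-downsampled at ``params.voxel_size_mm`` for speed.  The first
    cloud is fixed; each subsequent cloud is refined against the
    accumulated merged cloud with point-to-plane ICP before being merged.
    The merged result is voxel-downsampled once more at the same size.

    Returns the merged cloud and the per-cloud refinement transforms
    (identity for the first).
    """
    if len(clouds) < 2:
        raise InvalidArgumentError("need at least two clouds to register")
    if len(clouds) != len(extrinsics):
        raise InvalidArgumentError("one extrinsic transform per cloud required")
    aligned = [voxel_downsample(apply_transform(c, T), params.voxel_size_mm)
               for c, T in zip(clouds, extrinsics)]
    refinements: list[RigidTransform] = [RigidTransform.identity()]
    merged = voxel_downsample(aligned[0], params.voxel_size_mm)
    pieces = [aligned[0]]
    for i in range(1, len(aligned)):
        target = estimate_normals(merged, k=min(normals_k, len(merged) - 1),
                                  viewpoint=merged.points.mean(axis=0))
        try:
            T_ref, _ = icp_point_to_plane(aligned[i], target,
                                          init=RigidTransform.identity(),
                                          params=params)
        except NoOverlapError as exc:
            raise NoOverlapError(
                f"no overlap refining cloud {i} against clouds 0..{i - 1}"
            ) from exc
        refined = apply_transform(aligned[i], T_ref)
        refinements.append(T_ref)
        pieces.append(refined)
        merged = voxel_downsample(
            PointCloud(points=np.vstack([merged.points, refined.points])),
            params.voxel_size_mm)
    points = np.vstack([c.points for c in pieces])
    colors = (np.vstack([c.colors for c in pieces])
              if all(c.colors is not None for c in pieces) else None)
    normals = (np.vstack([c.normals for c in pieces])
               if all(c.normals is not None for c in pieces) else None)
    fused = PointCloud(points=points, colors=colors, normals=normals)
    return voxel_downsample(fused, params.voxel_size_mm), refinements
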