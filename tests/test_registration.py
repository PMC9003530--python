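"""Voxel downsampling, normal estimation and point-to-plane ICP."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from limbscan.calibration import RigidTransform
from limbscan.errors import InvalidArgumentError, NoOverlapError
from limbscan.geometry import PointCloud
from limbscan.registration import (ICPParams, apply_transform,
                                   estimate_normals, icp_point_to_plane,
                                   pairwise_register,
                                   point_to_plane_objective, voxel_downsample)


def rot_z(deg):
    a = np.radians(deg)
    return np.array([[np.cos(a), -np.sin(a), 0],
                     [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])


def bumpy_plane(rng, n=4000, extent=100.0):
    """Dense plane-plus-bumps sample: enough relief to lock all 6 DOF."""
    xy = rng.uniform(-extent / 2, extent / 2, (n, 2))
    z = (6 * np.sin(xy[:, 0] / 11) + 5 * np.cos(xy[:, 1] / 7)
         + 3 * np.sin(xy[:, 0] * xy[:, 1] / 450))
    return np.column_stack([xy, z])


# -- apply_transform ---------------------------------------------------------

def test_apply_transform():
    cloud = PointCloud(points=[[0.0, 0, 0]],
                       normals=[[0.0, 0, 1]], colors=[[0.5, 0.5, 0.5]])
    ident = apply_transform(cloud, RigidTransform.identity())
    assert np.allclose(ident.points, cloud.points)
    T = RigidTransform(np.eye(3), np.array([1.0, 2, 3]))
    moved = apply_transform(cloud, T)
    assert np.allclose(moved.points, [[1, 2, 3]])
    assert np.allclose(moved.normals, [[0, 0, 1]])   # translation-invariant
    assert np.allclose(moved.colors, cloud.colors)


def test_apply_transform_composition(rng):
    cloud = PointCloud(points=rng.standard_normal((50, 3)) * 10)
    T1 = RigidTransform(rot_z(30), rng.standard_normal(3))
    T2 = RigidTransform(rot_z(-70), rng.standard_normal(3))
    a = apply_transform(apply_transform(cloud, T1), T2)
    b = apply_transform(cloud, T2 @ T1)
    assert np.allclose(a.points, b.points, atol=1e-9)


# -- voxel_downsample --------------------------------------------------------

def test_voxel_downsample_single_and_grid():
    pts = np.array([[0.1, 0.1, 0.1], [0.4, 0.2, 0.3], [0.2, 0.4, 0.2]])
    out = voxel_downsample(PointCloud(points=pts), 1.0)
    assert len(out) == 1
    assert np.allclose(out.points[0], pts.mean(axis=0))
    grid = np.stack(np.meshgrid(*[np.arange(0, 50, 10.0)] * 3),
                    axis=-1).reshape(-1, 3) + 1.0
    out = voxel_downsample(PointCloud(points=grid), 2.0)
    assert len(out) == len(grid)            # one point per voxel already


def test_voxel_downsample_matches_bucketing_oracle(rng):
    pts = rng.uniform(-50, 50, (1000, 3))
    for size in (1.0, 3.0, 7.5):
        out = voxel_downsample(PointCloud(points=pts), size)
        keys = {tuple(k) for k in np.floor(pts / size).astype(int)}
        assert len(out) == len(keys)


def test_voxel_downsample_idempotent_in_count(rng):
    pts = rng.uniform(-50, 50, (2000, 3))
    once = voxel_downsample(PointCloud(points=pts), 4.0)
    twice = voxel_downsample(once, 4.0)
    assert len(twice) == len(once)


def test_voxel_downsample_renormalises_normals(rng):
    n = rng.standard_normal((200, 3))
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    cloud = PointCloud(points=rng.uniform(0, 10, (200, 3)), normals=n)
    out = voxel_downsample(cloud, 5.0)
    assert np.allclose(np.linalg.norm(out.normals, axis=1), 1.0, atol=1e-9)


# -- estimate_normals --------------------------------------------------------

def test_estimate_normals_plane(rng):
    pts = np.column_stack([rng.uniform(0, 100, (500, 2)), np.zeros(500)])
    out = estimate_normals(PointCloud(points=pts), k=10,
                           viewpoint=(50, 50, 1000))
    assert np.allclose(np.abs(out.normals[:, 2]), 1.0, atol=1e-9)
    assert (out.normals[:, 2] > 0).all()       # oriented toward viewpoint


def test_estimate_normals_sphere_radial(rng):
    v = rng.standard_normal((10_000, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = 50.0 * v
    out = estimate_normals(PointCloud(points=pts), k=12, viewpoint=(0, 0, 0))
    # viewpoint at the centre flips normals inward: compare to −radial
    cosang = np.einsum("ij,ij->i", out.normals, -v)
    assert np.degrees(np.arccos(np.clip(cosang, -1, 1))).max() < 5.0


def test_estimate_normals_four_coplanar_points():
    pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
    out = estimate_normals(PointCloud(points=pts), k=3, viewpoint=(0, 0, 5))
    assert np.allclose(out.normals, [[0, 0, 1]] * 4, atol=1e-9)
    with pytest.raises(InvalidArgumentError):
        estimate_normals(PointCloud(points=pts), k=4)


# -- ICP ---------------------------------------------------------------------

def test_icp_source_equals_target(rng):
    pts = bumpy_plane(rng)
    target = estimate_normals(PointCloud(points=pts), k=10,
                              viewpoint=(0, 0, 1000))
    T, E = icp_point_to_plane(target, target)
    assert np.allclose(T.as_matrix(), np.eye(4), atol=1e-9)
    assert E == pytest.approx(0.0, abs=1e-12)


def test_icp_objective_single_correspondence():
    # one source point 1 mm off a plane point along its normal: E = 1
    target = PointCloud(points=[[0.0, 0, 0]], normals=[[0.0, 0, 1]])
    source = PointCloud(points=[[0.0, 0, 1]])
    E, *_ = point_to_plane_objective(source, target, cKDTree(target.points),
                                     RigidTransform.identity(), 10.0)
    assert E == pytest.approx(1.0)


def test_icp_recovers_small_perturbation(rng):
    """A 2° / 3 mm misalignment is recovered to within 0.1° / 0.2 mm."""
    pts = bumpy_plane(rng)
    target = estimate_normals(PointCloud(points=pts), k=10,
                              viewpoint=(0, 0, 1000))
    T_true = RigidTransform(rot_z(2.0), np.array([3.0, 0.0, 0.0]))
    source = PointCloud(points=T_true.apply(pts))
    T, E = icp_point_to_plane(source, target,
                              params=ICPParams(max_correspondence_mm=15))
    residual = T @ T_true
    angle = np.degrees(np.arccos(
        np.clip((np.trace(residual.rotation) - 1) / 2, -1, 1)))
    assert angle < 0.1
    assert np.linalg.norm(residual.translation) < 0.2


def test_icp_monotone_and_bounded_by_init(rng):
    """E at the returned transform never exceeds E at the init."""
    pts = bumpy_plane(rng, n=2000)
    target = estimate_normals(PointCloud(points=pts), k=10,
                              viewpoint=(0, 0, 1000))
    init = RigidTransform(rot_z(3.0), np.array([2.0, -2.0, 1.0]))
    source = PointCloud(points=pts)
    tree = cKDTree(target.points)
    E_init, *_ = point_to_plane_objective(source, target, tree, init, 15.0)
    T, E_final = icp_point_to_plane(source, target, init=init,
                                    params=ICPParams(max_correspondence_mm=15))
    assert E_final <= E_init + 1e-9


def test_icp_no_overlap_and_bad_inputs(rng):
    pts = rng.uniform(0, 10, (200, 3))
    target = estimate_normals(PointCloud(points=pts), k=5, viewpoint=(0, 0, 100))
    far = PointCloud(points=pts + 1e6)
    with pytest.raises(NoOverlapError):
        icp_point_to_plane(far, target)
    with pytest.raises(InvalidArgumentError):
        icp_point_to_plane(PointCloud(points=pts), PointCloud(points=pts))


# -- pairwise_register -------------------------------------------------------

def test_pairwise_register_prealigned_is_concatenation(rng):
    pts = bumpy_plane(rng, n=3000)
    cloud = PointCloud(points=pts)
    fused, refinements = pairwise_register(
        [cloud, cloud], [RigidTransform.identity()] * 2,
        ICPParams(voxel_size_mm=2.0))
    assert np.allclose(refinements[1].as_matrix(), np.eye(4), atol=1e-6)
    plain = voxel_downsample(PointCloud(points=np.vstack([pts, pts])), 2.0)
    assert abs(len(fused) - len(plain)) <= 0.02 * len(plain)


def test_pairwise_register_zero_overlap_names_pair(rng):
    a = PointCloud(points=rng.uniform(0, 10, (300, 3)))
    b = PointCloud(points=rng.uniform(0, 10, (300, 3)) + 1e5)
    with pytest.raises(NoOverlapError, match="cloud 1"):
        pairwise_register([a, b], [RigidTransform.identity()] * 2)
    with pytest.raises(InvalidArgumentError):
        pairwise_register([a], [RigidTransform.identity()])
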