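"""Scene simulator: rig poses, analytic rendering, noise, checkerboard."""

import numpy as np
import pytest

from limbscan.calibration import RigidTransform
from limbscan.errors import VisibilityError
from limbscan.geometry import deproject
from limbscan.meshing import mesh_volume
from limbscan.metrics import cross_section_extent
from limbscan.synthetic import (LimbPhantom, RigLayout, add_depth_noise,
                                default_intrinsics, ground_truth_mesh,
                                make_rig, render_checkerboard, render_rgbd)


@pytest.fixture(scope="module")
def small_layout():
    return RigLayout(width_px=160, height_px=90)


# -- rig poses ---------------------------------------------------------------

def test_make_rig_pose_count_and_symmetry():
    poses = make_rig(RigLayout())
    assert len(poses) == 5
    p0, p2 = poses[0].translation, poses[2].translation
    assert np.allclose(p0[:2], (305, 0)) and np.allclose(p2[:2], (-305, 0))
    # consecutive radial poses are 90° apart about the rig axis
    Rz90 = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
    for a, b in zip(poses[:3], poses[1:4]):
        assert np.allclose(b.rotation, Rz90 @ a.rotation, atol=1e-12)
        assert np.allclose(b.translation, Rz90 @ a.translation, atol=1e-9)


def test_make_rig_axes_hit_rig_axis():
    for pose in make_rig(RigLayout()):
        origin = pose.translation
        z_axis = pose.rotation[:, 2]
        # distance from the line origin + t·z_axis to the z axis is the
        # norm of the xy part of origin − t*z with t chosen optimally;
        # both radial and end cameras aim straight through the axis
        t = -(origin[0] * z_axis[0] + origin[1] * z_axis[1]) / \
            max(z_axis[0] ** 2 + z_axis[1] ** 2, 1e-30)
        closest = origin + t * z_axis if z_axis[:2].any() else origin * [0, 0, 1]
        assert np.hypot(*closest[:2]) < 1e-9 or not z_axis[:2].any()
        # right-handed orthonormal pose
        R = pose.rotation
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0)


# -- rendering ---------------------------------------------------------------

def test_render_center_pixel_depth_on_axis(phantom):
    """An on-axis end view sees the cap apex at standoff − 0 range."""
    K = default_intrinsics(161, 91)  # odd size: integer principal point
    pose = RigidTransform(np.eye(3), np.array([0.0, 0.0, phantom.tip_z - 230]))
    frame, sil = render_rgbd(phantom, pose, K)
    cy, cx = int(K.cy), int(K.cx)
    assert sil[cy, cx]
    assert frame.depth[cy, cx] == pytest.approx(230.0, abs=1e-9)


def test_render_depth_matches_analytic_intersection(phantom, small_layout):
    """Rendered depths re-solve the ray equation to 1e-6 mm."""
    pose = make_rig(small_layout)[0]
    K = small_layout.intrinsics
    frame, sil = render_rgbd(phantom, pose, K)
    vs, us = np.nonzero(sil)
    pick = slice(0, len(vs), 37)
    d_cam = np.column_stack([(us[pick] - K.cx) / K.fx,
                             (vs[pick] - K.cy) / K.fy,
                             np.ones(len(us[pick]))])
    d_world = d_cam @ pose.rotation.T
    o = np.broadcast_to(pose.translation, d_world.shape)
    t, hit = phantom.intersect(o, d_world)
    assert hit.all()
    assert np.abs(frame.depth[vs[pick], us[pick]] - t).max() < 1e-6


def test_render_deprojected_points_lie_on_surface(phantom, small_layout):
    pose = make_rig(small_layout)[1]
    frame, sil = render_rgbd(phantom, pose, small_layout.intrinsics)
    cloud = deproject(frame, sil)
    world = pose.apply(cloud.points)
    # each point's cylindrical radius equals the profile radius at its z
    r = np.hypot(world[:, 0], world[:, 1])
    on_lathe = np.abs(r - phantom.radius_at(world[:, 2]))
    on_base = np.abs(world[:, 2] - phantom.base_z)
    assert np.minimum(on_lathe, on_base).max() < 1e-6


def test_render_backdrop_pixels(phantom, small_layout):
    pose = make_rig(small_layout)[0]
    frame, sil = render_rgbd(phantom, pose, small_layout.intrinsics)
    assert np.all(frame.depth[~sil] == phantom.backdrop_distance_mm)
    assert np.all(frame.color[~sil] == np.array(phantom.backdrop_color))
    assert np.all(frame.color[sil] == np.array(phantom.color))


def test_cylinder_silhouette_width(small_layout):
    """A broadside cylinder's silhouette width in px matches 2r/res."""
    cyl = LimbPhantom(profile=((50.0, 50.0), (200.0, 50.0)))
    layout = small_layout
    pose = make_rig(layout)[0]
    frame, sil = render_rgbd(cyl, pose, layout.intrinsics)
    # vertical stance: the cylinder's length runs along image columns (u),
    # its angular width along rows (v); measure a mid-length column
    cols = np.nonzero(sil.any(axis=0))[0]
    mid = cols[len(cols) // 2]
    width_px = sil[:, mid].sum()
    # perspective: half-angle to the tangent of a cylinder of radius r
    half_angle = np.arcsin(50.0 / layout.frame_radius_mm)
    expected = 2 * np.tan(half_angle) * layout.intrinsics.fy
    assert abs(width_px - expected) <= 2.0


# -- depth noise -------------------------------------------------------------

def test_depth_noise_contract(phantom, small_layout):
    pose = make_rig(small_layout)[0]
    frame, _ = render_rgbd(phantom, pose, small_layout.intrinsics)
    assert np.array_equal(add_depth_noise(frame, 0.0).depth, frame.depth)
    a = add_depth_noise(frame, 0.02, seed=5)
    b = add_depth_noise(frame, 0.02, seed=5)
    assert np.array_equal(a.depth, b.depth)
    c = add_depth_noise(frame, 0.02, seed=6)
    assert not np.array_equal(a.depth, c.depth)


def test_depth_noise_sigma_at_two_meters():
    """Empirical σ over 10⁵ draws at z = 2 m is 40 mm within 2%."""
    from limbscan.geometry import CameraIntrinsics, RGBDFrame
    h, w = 250, 400   # 10⁵ pixels
    K = CameraIntrinsics(width_px=w, height_px=h, fx=100, fy=100,
                         cx=w / 2 - 0.5, cy=h / 2 - 0.5)
    frame = RGBDFrame(color=np.zeros((h, w, 3), np.uint8),
                      depth=np.full((h, w), 2000.0), intrinsics=K)
    noisy = add_depth_noise(frame, 0.02, seed=123)
    sigma = (noisy.depth - 2000.0).std()
    assert sigma == pytest.approx(40.0, rel=0.02)


# -- checkerboard ------------------------------------------------------------

def test_checkerboard_at_camera_origin_is_model():
    from limbscan.calibration import checkerboard_model
    pose = RigidTransform(np.eye(3), np.array([0.0, 0.0, 500.0]))
    cam = RigidTransform.identity()
    # board placed in front of a camera at the world origin
    (obs,) = render_checkerboard(pose, [cam])
    assert obs.shape == (54, 3)
    assert np.allclose(obs, checkerboard_model() + [0, 0, 500], atol=1e-12)


def test_checkerboard_behind_camera_raises():
    pose = RigidTransform(np.eye(3), np.array([0.0, 0.0, -500.0]))
    with pytest.raises(VisibilityError):
        render_checkerboard(pose, [RigidTransform.identity()])


def test_checkerboard_noise_determinism():
    pose = RigidTransform(np.eye(3), np.array([0.0, 0.0, 500.0]))
    cams = make_rig(RigLayout())
    a = render_checkerboard(pose, cams, noise_sigma_mm=0.5, seed=9)
    b = render_checkerboard(pose, cams, noise_sigma_mm=0.5, seed=9)
    for x, y in zip(a, b):
        assert np.array_equal(x, y)


# -- ground-truth mesh -------------------------------------------------------

def test_ground_truth_mesh_watertight_at_various_resolutions(phantom):
    for n_theta, n_height in ((32, 16), (64, 32), (128, 64)):
        m = ground_truth_mesh(phantom, n_theta=n_theta, n_height=n_height)
        assert m.is_watertight
        assert m.euler_characteristic == 2


def test_ground_truth_cylinder_volume():
    cyl = LimbPhantom(profile=((50.0, 50.0), (150.0, 50.0)))
    m = ground_truth_mesh(cyl, n_theta=256, n_height=64)
    analytic = np.pi * 50 ** 2 * 100 + 2 / 3 * np.pi * 50 ** 3
    assert mesh_volume(m) == pytest.approx(analytic, rel=0.01)


def test_ground_truth_cross_sections_match_profile(phantom, phantom_mesh):
    for h in (70.0, 125.0, 190.0, 230.0):
        assert cross_section_extent(phantom_mesh, h) == pytest.approx(
            2 * float(phantom.radius_at(h)), abs=0.5)
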