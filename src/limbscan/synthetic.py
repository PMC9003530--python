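"""Synthetic stand-in for the physical multi-camera scanning rig.

Generates everything the pipeline would get from hardware: a parametric
limb-like phantom (a piecewise-linear radius profile revolved about the rig
axis, closed by a hemispherical distal cap and a flat proximal base), a
ring of inward-looking RGB-D cameras plus an end-view camera, per-pixel
ray-cast color/depth renders against a green backdrop, checkerboard corner
observations for extrinsic calibration, and a distance-proportional depth
noise model.

Rendering is analytic, not rasterised: every camera ray is intersected in
closed form with the revolved surface (a quadratic per profile segment),
the cap sphere and the base disk, so rendered depths agree with the true
geometry to floating-point precision and every downstream stage can be
tested against exact oracles.

World frame: the rig axis is +z; the phantom occupies z ∈ [tip, base] with
the distal cap at the bottom, mirroring a residuum hanging into the frame;
the end camera sits below the tip looking up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibration import RigidTransform, checkerboard_model
from .errors import InvalidArgumentError, VisibilityError
from .geometry import CameraIntrinsics, RGBDFrame
from .meshing import TriangleMesh

__all__ = [
    "LimbPhantom",
    "RigLayout",
    "default_intrinsics",
    "make_rig",
    "render_rgbd",
    "add_depth_noise",
    "render_checkerboard",
    "ground_truth_mesh",
]

#: Sensor field of view (degrees), horizontal × vertical.
FOV_H_DEG = 69.4
FOV_V_DEG = 42.5

SKIN_RGB = (224, 172, 140)
GREEN_RGB = (40, 180, 70)

# Default residuum-like radius profile (z from the cap equator up to the
# base): 75 mm maximum radius, 250 mm overall length including the 60 mm
# hemispherical cap.  r(z) is concave, so the silhouette is convex from
# every rig viewpoint.
DEFAULT_PROFILE = ((60.0, 60.0), (120.0, 70.0), (190.0, 75.0), (250.0, 65.0))


@dataclass(frozen=True)
class LimbPhantom:
    """Convex solid of revolution standing in for a residual limb.

    ``profile`` lists (z, radius) control points in ascending z; the surface
    is the linear interpolation revolved about the z axis, closed below by a
    hemisphere of the first control radius and above by a flat disk.
    """

    profile: tuple[tuple[float, float], ...] = DEFAULT_PROFILE
    color: tuple[int, int, int] = SKIN_RGB
    backdrop_color: tuple[int, int, int] = GREEN_RGB
    backdrop_distance_mm: float = 600.0

    def __post_init__(self):
        zs = [z for z, _ in self.profile]
        rs = [r for _, r in self.profile]
        if len(self.profile) < 2 or any(r <= 0 for r in rs):
            raise InvalidArgumentError("profile needs ≥ 2 points, radii > 0")
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise InvalidArgumentError("profile z values must be ascending")

    @property
    def cap_center_z(self) -> float:
        return self.profile[0][0]

    @property
    def cap_radius(self) -> float:
        return self.profile[0][1]

    @property
    def tip_z(self) -> float:
        return self.cap_center_z - self.cap_radius

    @property
    def base_z(self) -> float:
        return self.profile[-1][0]

    @property
    def base_radius(self) -> float:
        return self.profile[-1][1]

    @property
    def length(self) -> float:
        return self.base_z - self.tip_z

    @property
    def max_radius(self) -> float:
        return max(r for _, r in self.profile)

    def radius_at(self, z) -> np.ndarray:
        """Analytic surface radius at height(s) z (cap, profile or 0)."""
        z = np.asarray(z, dtype=np.float64)
        zs = np.array([p[0] for p in self.profile])
        rs = np.array([p[1] for p in self.profile])
        r = np.interp(z, zs, rs)
        in_cap = (z >= self.tip_z) & (z < self.cap_center_z)
        cap_r = np.sqrt(np.maximum(self.cap_radius ** 2
                                   - (z - self.cap_center_z) ** 2, 0.0))
        r = np.where(in_cap, cap_r, r)
        return np.where((z < self.tip_z) | (z > self.base_z), 0.0, r)

    # -- analytic ray casting -------------------------------------------------

    def intersect(self, origins: np.ndarray, dirs: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
        """First intersection of rays o + t·d with the phantom surface.

        Returns (t, hit): the smallest parameter t > 0 per ray (inf where
        the ray misses) and a boolean hit flag.  Directions need not be
        normalised; t is in units of |d|.
        """
        o = np.atleast_2d(np.asarray(origins, dtype=np.float64))
        d = np.atleast_2d(np.asarray(dirs, dtype=np.float64))
        t_best = np.full(len(d), np.inf)

        # revolved profile segments: x² + y² = (a + b z)² on z ∈ [z0, z1]
        for (z0, r0), (z1, r1) in zip(self.profile, self.profile[1:]):
            b = (r1 - r0) / (z1 - z0)
            a = r0 - b * z0
            A = d[:, 0] ** 2 + d[:, 1] ** 2 - (b * d[:, 2]) ** 2
            rr = a + b * o[:, 2]
            B = 2 * (o[:, 0] * d[:, 0] + o[:, 1] * d[:, 1] - b * d[:, 2] * rr)
            C = o[:, 0] ** 2 + o[:, 1] ** 2 - rr ** 2
            for t in _quadratic_roots(A, B, C):
                z = o[:, 2] + t * d[:, 2]
                ok = np.isfinite(t) & (t > 1e-9) & (z >= z0) & (z <= z1)
                t_best = np.where(ok & (t < t_best), t, t_best)

        # hemispherical cap (lower half of the sphere at the first control pt)
        cz, cr = self.cap_center_z, self.cap_radius
        oc = o - np.array([0.0, 0.0, cz])
        A = np.einsum("ij,ij->i", d, d)
        B = 2 * np.einsum("ij,ij->i", oc, d)
        C = np.einsum("ij,ij->i", oc, oc) - cr ** 2
        for t in _quadratic_roots(A, B, C):
            z = o[:, 2] + t * d[:, 2]
            ok = np.isfinite(t) & (t > 1e-9) & (z <= cz + 1e-12)
            t_best = np.where(ok & (t < t_best), t, t_best)

        # flat base disk at the top
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (self.base_z - o[:, 2]) / d[:, 2]
        x = o[:, 0] + t * d[:, 0]
        y = o[:, 1] + t * d[:, 1]
        ok = np.isfinite(t) & (t > 1e-9) & (x ** 2 + y ** 2
                                            <= self.base_radius ** 2)
        t_best = np.where(ok & (t < t_best), t, t_best)

        return t_best, np.isfinite(t_best)

    def surface_normal(self, points: np.ndarray) -> np.ndarray:
        """Exact outward unit normal at surface point(s)."""
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        n = np.zeros_like(p)
        z = p[:, 2]
        on_base = np.isclose(z, self.base_z, atol=1e-6)
        n[on_base] = (0.0, 0.0, 1.0)
        in_cap = (z < self.cap_center_z) & ~on_base
        cap_vec = p[in_cap] - np.array([0.0, 0.0, self.cap_center_z])
        n[in_cap] = cap_vec / np.linalg.norm(cap_vec, axis=1, keepdims=True)
        rest = ~(on_base | in_cap)
        if rest.any():
            zs = np.array([q[0] for q in self.profile])
            rs = np.array([q[1] for q in self.profile])
            seg = np.clip(np.searchsorted(zs, z[rest], side="right") - 1,
                          0, len(zs) - 2)
            b = (rs[seg + 1] - rs[seg]) / (zs[seg + 1] - zs[seg])
            r = rs[seg] + b * (z[rest] - zs[seg])
            # gradient of x² + y² − r(z)²: (2x, 2y, −2 r r')
            g = np.column_stack([p[rest, 0], p[rest, 1], -r * b])
            n[rest] = g / np.linalg.norm(g, axis=1, keepdims=True)
        return n


def _quadratic_roots(A, B, C):
    """Both real roots of A t² + B t + C = 0 per element (linear fallback
    when A ≈ 0); NaN/inf where there is no real root."""
    A, B, C = (np.asarray(x, dtype=np.float64) for x in (A, B, C))
    disc = B ** 2 - 4 * A * C
    with np.errstate(invalid="ignore", divide="ignore"):
        sq = np.sqrt(disc)
        t1 = (-B - sq) / (2 * A)
        t2 = (-B + sq) / (2 * A)
        t_lin = -C / B
    linear = np.abs(A) < 1e-14
    t1 = np.where(linear, t_lin, t1)
    t2 = np.where(linear, np.inf, t2)
    bad = (disc < 0) & ~linear
    t1 = np.where(bad, np.inf, t1)
    t2 = np.where(bad, np.inf, t2)
    t1 = np.where(np.isnan(t1), np.inf, t1)
    t2 = np.where(np.isnan(t2), np.inf, t2)
    return t1, t2


@dataclass(frozen=True)
class RigLayout:
    """Geometry of the camera frame.

    Four radial cameras sit every 90° on a circle of ``frame_radius_mm``
    (inner frame diameter 610 mm), optical axes aimed at the rig axis, in a
    vertical stance so the wider image dimension covers the limb's length;
    a fifth end camera on the axis views the distal cap.
    """

    frame_radius_mm: float = 305.0
    n_radial: int = 4
    end_camera: bool = True
    camera_height_mm: float = 125.0
    end_standoff_mm: float = 230.0
    width_px: int = 1280
    height_px: int = 720

    def __post_init__(self):
        if self.frame_radius_mm <= 0 or self.n_radial < 1:
            raise InvalidArgumentError("invalid rig layout")

    @property
    def n_cameras(self) -> int:
        return self.n_radial + (1 if self.end_camera else 0)

    @property
    def intrinsics(self) -> CameraIntrinsics:
        return default_intrinsics(self.width_px, self.height_px)


def default_intrinsics(width_px: int = 1280, height_px: int = 720
                       ) -> CameraIntrinsics:
    """Pinhole intrinsics for the sensor's 69.4° × 42.5° field of view at
    any raster size (focal lengths scale with the pixel count)."""
    fx = (width_px / 2.0) / math.tan(math.radians(FOV_H_DEG) / 2.0)
    fy = (height_px / 2.0) / math.tan(math.radians(FOV_V_DEG) / 2.0)
    return CameraIntrinsics(width_px=width_px, height_px=height_px,
                            fx=fx, fy=fy,
                            cx=(width_px - 1) / 2.0, cy=(height_px - 1) / 2.0)


def make_rig(layout: RigLayout = RigLayout()) -> list[RigidTransform]:
    """Ground-truth world-from-camera poses for the rig.

    Radial camera i sits at angle i·(360°/n) on the frame circle with its
    optical axis through the rig axis; its image u axis runs along −z
    (vertical stance).  The end camera sits below the phantom tip on the
    axis looking up.
    """
    poses = []
    for i in range(layout.n_radial):
        th = 2.0 * math.pi * i / layout.n_radial
        c, s = math.cos(th), math.sin(th)
        pos = np.array([layout.frame_radius_mm * c,
                        layout.frame_radius_mm * s,
                        layout.camera_height_mm])
        z_cam = np.array([-c, -s, 0.0])          # toward the rig axis
        x_cam = np.array([0.0, 0.0, -1.0])       # image u along world −z
        y_cam = np.cross(z_cam, x_cam)
        R = np.column_stack([x_cam, y_cam, z_cam])
        poses.append(RigidTransform(R, pos))
    if layout.end_camera:
        pos = np.array([0.0, 0.0, -layout.end_standoff_mm])
        R = np.column_stack([(1.0, 0.0, 0.0), (0.0, 1.0, 0.0),
                             (0.0, 0.0, 1.0)])
        poses.append(RigidTransform(R, pos))
    return poses


def render_rgbd(phantom: LimbPhantom, pose: RigidTransform,
                intrinsics: CameraIntrinsics
                ) -> tuple[RGBDFrame, np.ndarray]:
    """Ray-cast one camera view: returns the RGB-D frame and the
    ground-truth silhouette mask (true exactly where the phantom is hit).

    Each pixel ray is intersected analytically with the phantom; rays that
    miss hit the green backdrop plane perpendicular to the optical axis at
    the phantom's backdrop distance.  Depth is the hit range along the
    optical axis in mm (float, no quantisation).
    """
    K = intrinsics
    u, v = np.meshgrid(np.arange(K.width_px), np.arange(K.height_px))
    # camera-frame directions scaled so the z component is 1: the ray
    # parameter is then the depth along the optical axis directly
    d_cam = np.stack([(u - K.cx) / K.fx, (v - K.cy) / K.fy,
                      np.ones_like(u, dtype=np.float64)], axis=-1)
    d_world = d_cam.reshape(-1, 3) @ pose.rotation.T
    o_world = np.broadcast_to(pose.translation, d_world.shape)
    t, hit = phantom.intersect(o_world, d_world)
    depth = np.where(hit, t, phantom.backdrop_distance_mm)
    silhouette = hit.reshape(K.height_px, K.width_px)
    depth = depth.reshape(K.height_px, K.width_px)
    color = np.empty((K.height_px, K.width_px, 3), dtype=np.uint8)
    color[:] = np.uint8(phantom.backdrop_color)
    color[silhouette] = np.uint8(phantom.color)
    frame = RGBDFrame(color=color, depth=depth, intrinsics=K)
    return frame, silhouette


def add_depth_noise(frame: RGBDFrame, relative_sigma: float = 0.02,
                    seed: int = 0) -> RGBDFrame:
    """Distance-proportional Gaussian depth noise.

    A depth z is perturbed with standard deviation
    σ(z) = relative_sigma · (z / 2000 mm) · z, matching a sensor accuracy
    specification of ``relative_sigma`` (2% by default) at a 2 m range and
    improving quadratically closer in.  Invalid (zero) depths are left
    untouched; the result is deterministic under a fixed seed.
    """
    if relative_sigma == 0:
        return RGBDFrame(color=frame.color.copy(), depth=frame.depth.copy(),
                         intrinsics=frame.intrinsics)
    rng = np.random.default_rng(seed)
    depth = frame.depth_mm
    sigma = relative_sigma * depth / 2000.0 * depth
    noisy = depth + rng.standard_normal(depth.shape) * sigma
    noisy = np.where(depth > 0, np.maximum(noisy, 0.0), 0.0)
    return RGBDFrame(color=frame.color.copy(), depth=noisy,
                     intrinsics=frame.intrinsics)


def render_checkerboard(board_pose: RigidTransform,
                        camera_poses: list[RigidTransform],
                        square_mm: float = 25.0,
                        inner_corners: tuple[int, int] = (6, 9),
                        noise_sigma_mm: float = 0.0,
                        seed: int = 0) -> list[np.ndarray]:
    """Ordered 3-D checkerboard corner observations for every camera.

    The board model (row-major inner corners, z = 0 in the board frame) is
    placed by ``board_pose`` (world-from-board) and expressed in each
    camera's frame; optional isotropic Gaussian noise emulates corner
    localisation error.  A corner behind any camera raises
    :class:`VisibilityError`.
    """
    model = checkerboard_model(*inner_corners, square_mm=square_mm)
    world = board_pose.apply(model)
    rng = np.random.default_rng(seed)
    out = []
    for i, pose in enumerate(camera_poses):
        cam = pose.inverse().apply(world)
        if np.any(cam[:, 2] <= 0):
            raise VisibilityError(f"board corner behind camera {i}")
        if noise_sigma_mm > 0:
            cam = cam + rng.normal(0.0, noise_sigma_mm, cam.shape)
        out.append(cam)
    return out


def ground_truth_mesh(phantom: LimbPhantom, n_theta: int = 128,
                      n_height: int = 64, n_cap: int = 32) -> TriangleMesh:
    """Watertight analytic mesh of the phantom (the evaluation oracle).

    The profile is revolved at ``n_theta`` angular steps; each linear
    profile segment is subdivided into ``n_height`` rings in proportion to
    its length and the cap into ``n_cap`` latitude rings.  The mesh closes
    with the cap apex below and a centroid fan over the flat base.
    """
    stations: list[tuple[float, float]] = []
    # cap latitudes from just above the apex up to the equator
    for j in range(1, n_cap + 1):
        phi = (math.pi / 2.0) * j / n_cap
        stations.append((phantom.cap_center_z - phantom.cap_radius * math.cos(phi),
                         phantom.cap_radius * math.sin(phi)))
    zs = [p[0] for p in phantom.profile]
    total = zs[-1] - zs[0]
    for (z0, _), (z1, _) in zip(phantom.profile, phantom.profile[1:]):
        k = max(2, int(round(n_height * (z1 - z0) / total)))
        for j in range(1, k + 1):
            z = z0 + (z1 - z0) * j / k
            stations.append((z, float(phantom.radius_at(z))))
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    rings = []
    for z, r in stations:
        rings.append(np.column_stack([r * np.cos(theta), r * np.sin(theta),
                                      np.full(n_theta, z)]))
    apex = np.array([[0.0, 0.0, phantom.tip_z]])
    top = np.array([[0.0, 0.0, phantom.base_z]])
    verts = np.vstack([apex] + rings + [top])
    faces = []
    # apex fan (outward winding: seen from below, apex fan runs clockwise)
    for j in range(n_theta):
        a, b = 1 + j, 1 + (j + 1) % n_theta
        faces.append((0, b, a))
    # quads between consecutive rings
    for i in range(len(rings) - 1):
        base0, base1 = 1 + i * n_theta, 1 + (i + 1) * n_theta
        for j in range(n_theta):
            j2 = (j + 1) % n_theta
            faces.append((base0 + j, base0 + j2, base1 + j))
            faces.append((base0 + j2, base1 + j2, base1 + j))
    # top fan
    top_i = len(verts) - 1
    base0 = 1 + (len(rings) - 1) * n_theta
    for j in range(n_theta):
        faces.append((base0 + j, base0 + (j + 1) % n_theta, top_i))
    return TriangleMesh(verts, np.array(faces, dtype=np.int64))
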