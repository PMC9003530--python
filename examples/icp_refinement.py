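"""Refine a deliberately misaligned phantom scan with point-to-plane ICP.

A surface sample of the phantom is rotated 2° (about an axis perpendicular
to its revolve axis) and shifted 3 mm, then registered back onto the
original with the point-to-plane objective E(T) = Σ ((p − T·q)·n_p)².
"""

import math

import numpy as np

from limbscan import ICPParams, PointCloud, RigidTransform, icp_point_to_plane
from limbscan.metrics import _sample_surface
from limbscan.synthetic import LimbPhantom, ground_truth_mesh

phantom = LimbPhantom()
mesh = ground_truth_mesh(phantom)
pts = _sample_surface(mesh, 12_000, np.random.default_rng(0))
target = PointCloud(points=pts, normals=phantom.surface_normal(pts))

a = math.radians(2.0)
Rx = np.array([[1, 0, 0],
               [0, math.cos(a), -math.sin(a)],
               [0, math.sin(a), math.cos(a)]])
T_true = RigidTransform(Rx, np.array([0.0, 3.0, 0.0]))
source = PointCloud(points=T_true.apply(
    _sample_surface(mesh, 12_000, np.random.default_rng(1))))

T, E = icp_point_to_plane(source, target,
                          params=ICPParams(max_correspondence_mm=15))
residual = T @ T_true
angle = math.degrees(math.acos(np.clip(
    (np.trace(residual.rotation) - 1) / 2, -1, 1)))

print(f"applied perturbation   2.000 deg / 3.000 mm")
print(f"residual after ICP     {angle:.3f} deg / "
      f"{np.linalg.norm(residual.translation):.3f} mm")
print(f"final objective E      {E:.3f} mm^2")
print()
print("The residual is the leftover misalignment after refinement: well")
print("under a tenth of a degree and a fifth of a millimetre.")
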