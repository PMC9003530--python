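"""Extrinsic calibration of the 5-camera rig from a shared checkerboard.

Every camera observes the same 6×9 board of 25 mm squares in 3-D; one
Kabsch solve per camera recovers its pose relative to the reference
camera.  With noiseless corners the recovery is exact; with 0.5 mm corner
noise the error stays far below a degree / a millimetre-scale offset.
"""

import numpy as np

from limbscan import RigidTransform, calibrate_rig, checkerboard_model
from limbscan.synthetic import RigLayout, make_rig, render_checkerboard

poses = make_rig(RigLayout())                       # ground-truth rig
truth = [poses[0].inverse() @ p for p in poses]
board = RigidTransform(np.eye(3), np.array([-60.0, -70.0, 290.0]))

for sigma in (0.0, 0.5):
    obs = render_checkerboard(board, poses, noise_sigma_mm=sigma, seed=4)
    est = calibrate_rig(obs, checkerboard_model())
    errs = [np.linalg.norm(T.translation - Tt.translation)
            for T, Tt in zip(est, truth)]
    print(f"corner noise {sigma:.1f} mm -> max translation error "
          f"{max(errs):.6f} mm over {len(est)} cameras")

print()
print("The first camera is the reference (identity); the noiseless case")
print("recovers the rig to machine precision because Kabsch is closed form.")
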