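"""Size the camera frame from a limb circumference measurement.

Given a 470 mm leg circumference and a 305 mm frame radius, compute the
camera standoff, the metric area one 69.4° × 42.5° camera covers there,
and the resulting image resolution.
"""

import limbscan as ls
from limbscan.geometry import truncate_decimals

circumference = 470.0          # mm, measured on the limb
frame_radius = 305.0           # mm, inner radius of the camera ring

diameter, radius = ls.circumference_to_radius(circumference)
standoff = ls.standoff_distance(frame_radius, round(radius))
width = ls.fov_extent(69.4, standoff)
height = ls.fov_extent(42.5, standoff)
res = ls.resolution(width, 1280)

print(f"limb diameter          {diameter:7.1f} mm  (radius {radius:.1f} mm)")
print(f"camera standoff        {standoff:7.1f} mm")
print(f"coverage at standoff   {width:7.2f} x {height:.2f} mm")
print(f"image resolution       {truncate_decimals(res):7.2f} mm/px")
print()
print("One camera at the 230 mm standoff images a 318.52 x 178.88 mm patch")
print("of the limb at better than a quarter millimetre per pixel.")
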