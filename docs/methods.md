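# Methods

This note records the models implemented in `limbscan`, the parameter
choices that matter, what the simulator does and does not emulate, and the
numerical decisions a maintainer would want written down.

## Coordinate and unit conventions

All lengths are millimetres.  Image pixels are 0-based with
(u, v) = (column, row) and the origin at the top-left; the camera frame is
right-handed with +z along the optical axis, +x right, +y down.  Depth
rasters store millimetres (16-bit on disk, `depth_scale` mm per unit,
default 1); depth 0 marks an invalid pixel and never deprojects.  Color
and depth are assumed pre-aligned pixel-for-pixel, as RGB-D sensors
deliver them after factory alignment — no epipolar alignment is
implemented.  The world frame of the simulator puts the rig axis on +z
with the phantom's distal cap at the bottom.

## Rig design geometry

The frame is sized from first principles: a limb circumference *c* gives
radius *r* = *c*/2π (470 mm → 74.8 mm); the standoff is the frame radius
minus the target radius (305 − 75 = 230 mm); a field of view θ covers
2 tan(θ/2)·*l* at standoff *l* (69.4° → 318.52 mm, 42.5° → 178.88 mm at
230 mm); and the resolution is coverage divided by pixel count
(318.52/1280 = 0.2488 mm/px).  Reported design figures are quoted by
truncation to two decimals (0.24 mm/px), matching how such figures are
conventionally printed; `truncate_decimals` implements this.  The cameras
stand vertically: the wider image dimension runs along the limb's length.

## Kabsch calibration

For matched sets P (reference) and Q, both are centred on their
centroids, H = P₀ᵀQ₀ is decomposed H = V S Wᵀ, and the optimal proper
rotation is V·diag(1, 1, d)·Wᵀ with d = sign det(W Vᵀ) — the transpose of
the row-vector textbook form, since `RigidTransform` acts on column
vectors.  The sign factor d forbids reflections even when a mirrored
correspondence set would fit better.  The translation is the least-squares
completion t = centroid(P) − R·centroid(Q).  Rig calibration runs one
solve per camera against the 6×9 board model (25 mm squares, row-major
corners, origin at the first inner corner — all configurable) and chains
through the board: extrinsic_i = (ref-from-board)∘(camera_i-from-board)⁻¹.
Camera 0 is the default reference.  The module consumes 3-D corner
coordinates (from the simulator, or from depth lookup at detected
corners); 2-D corner detection is out of scope, which keeps calibration
hardware-free and exactly testable.

Monte-Carlo behaviour: with 0.5 mm isotropic corner noise on the default
rig the ensemble mean errors are ≈0.12° and ≈0.7 mm.  Single draws of the
translation error can reach a few millimetres because board-tilt noise is
amplified by the ~0.5 m lever arm from the board to the farthest camera;
accuracy statements are therefore about the ensemble mean.

## Segmentation

Stage order: depth cut (0 < z ≤ 500 mm) ∧ HSV color removal → Otsu
binarisation → largest region → iterated median → iterated erosion →
bitwise mask application.  Decisions:

- **Otsu input**: the grayscale (Rec. 709 luma) of the color raster
  restricted to the depth∧color support, zeros outside; Otsu over a
  256-bin histogram, exhaustively equivalent to minimising the
  within-class variance, ties to the smallest threshold, binarisation by
  `value > th`.  A constant support (uniform brightness) falls back to
  the support itself.
- **HSV bounds**: H ∈ [0, 360) with wrap-around allowed, S, V ∈ [0, 1];
  default green range H ∈ [70, 170], S ≥ 0.25, V ≥ 0.2.
- **Median filter** on the binary mask: majority vote over the window
  (window count is odd, so no ties), borders by symmetric reflection,
  implemented as a box count for speed and tested against the naive
  sliding-window median.
- **Erosion**: out-of-image pixels count false, so each pass also strips
  the raster border.
- **Connectivity** 8; size ties broken by earliest first pixel in
  row-major scan order.
- The final mask is forced inside the depth∧color support (the median can
  otherwise bleed across the silhouette boundary).
- Filter sizes are pixel quantities defined at the native 1280-px width;
  `SegmentationConfig.scaled_to(width)` rescales the median window and
  erosion depth proportionally so reduced-resolution captures lose the
  same metric rim.  A mask that empties at any stage raises an error
  naming the stage; region selection accepts no silent fallback.

## Registration

Extrinsics give the global alignment; every aligned cloud is
voxel-downsampled (cubes anchored at the origin, centroid per occupied
voxel, attributes averaged, normals re-normalised) before refinement.
Cloud 1 is fixed; cloud i is refined against the accumulated merged cloud
— refining against everything fused so far rather than only the previous
view tightens loop closure around the ring — then merged, with a final
downsample at the same voxel size.

Point-to-plane ICP: correspondences are nearest target neighbours within
`max_correspondence_mm` (default 10 mm; 15 mm is used in the wider-basin
recovery experiments); each iteration solves the 6×6 normal equations of
the linearised objective (small-angle rotation, Cholesky with a 1e-12
ridge for the rank-deficient symmetric-target case) and applies the exact
Rodrigues exponential of the update.  Updates that fail to decrease E are
rejected and stop the loop, so the returned objective never exceeds the
objective at the initial guess.  Defaults: 50 iterations, relative
tolerance 1e-6, voxel 2 mm.

Normals come from PCA over k = 20 nearest neighbours (smallest-eigenvalue
eigenvector), oriented toward a viewpoint — the camera origin for
per-view clouds, which makes them outward surface normals.

A note on symmetry: the default phantom is a surface of revolution, so a
rotation about its own axis is invisible to any registration objective;
recovery experiments perturb about a perpendicular axis.

## Surface reconstruction

The fused oriented cloud induces a truncated signed distance field on a
`grid_resolution`³ lattice (default 128³ at full scale, 96³ in the
reduced-scale experiments) over the bounding box padded by 5%: at node g
with nearest point p and normal n, the field is clamp(n·(g − p),
±bandwidth), bandwidth defaulting to 3 grid cells, followed by a 1-cell
Gaussian smoothing and marching cubes at the zero level.  Face windings
are made consistent and outward.  The backend is pluggable — any
callable with the oriented-cloud → mesh contract can replace it.

Where the scan saw no data (chiefly the base resting on the table) the
extracted surface has boundary loops; `close_mesh` caps each with a
centroid fan, leaving existing vertices untouched.  The flat base this
creates is expected and sits below the measurement region of interest.
Watertightness is defined as every edge shared by exactly two faces;
volume is the orientation-corrected signed tetrahedron sum.

## Validation metrics

Dice = 2|A∩B|/(|A|+|B|) on binary masks.  The Hausdorff distance is
symmetric, on point sets or on true-pixel centre coordinates of masks
(pixels for masks, convertible to mm through the system resolution).
Mesh-vs-mesh distances use area-weighted uniform surface samples (default
100 000 per surface) and report the full summary row — min, quartiles
(linear interpolation between order statistics, the default convention of
`numpy.percentile`), mean, max, IQR = q3 − q1, and RMS = sqrt(mean x²) of
the data themselves.  Per-point nearest distances are exportable for
distance heat maps.  `cross_section_extent` slices the mesh with a plane
and projects the section outline on a direction, reproducing a caliper
diameter at a chosen height.

## The simulator

The phantom is a piecewise-linear radius profile revolved about the rig
axis — default control points (60, 60), (120, 70), (190, 75), (250, 65) mm
with a 60 mm hemispherical distal cap and a flat base: 250 mm long, 75 mm
maximum radius, radius profile concave so the silhouette is convex from
every rig viewpoint (the regime the scanner targets; occlusion handling
for non-convex targets is out of scope).  Rendering intersects every
pixel ray with the revolved segments (one quadratic each), the cap sphere
and the base disk in closed form — no rasterisation or z-buffer — so
rendered depths match the true geometry to ~1e-9 mm and downstream stages
can be tested against exact oracles.  Rays that miss hit a green backdrop
plane 600 mm from the camera, which the 500 mm depth threshold separates.
Depth noise is Gaussian with σ(z) = σ_rel·(z/2000)·z, i.e. a sensor
specified at σ_rel (default 2%) of range at 2 m, improving quadratically
closer in; all noise is seeded.

What the simulator does **not** emulate: stereo-matching artefacts
(speckle dropout, edge fattening, multi-camera projector interference),
lens distortion, exposure and illumination variation, soft-tissue motion,
and checkerboard corner *detection* (it emits exact or
Gaussian-perturbed 3-D corners).  Passing end-to-end tests therefore
demonstrate the correctness and noise tolerance of the algorithms, not
the hardware error budget of a physical rig.

## Problem sizes and determinism

The test suite and the acceptance script render at 320×180 (the native
69.4°×42.5° field of view, 4× fewer pixels per side than the 1280×720
sensor) and reconstruct on a 96³ lattice; these sizes keep the full
pipeline under ~20 s per run while leaving the median surface error well
below a millimetre, against a grid cell of ~3.3 mm.  Every random draw —
rendering noise, corner noise, surface sampling, Monte-Carlo seeds —
derives from an explicit seed, and file writers are deterministic, so a
re-run of a session reproduces its outputs byte for byte.

## Known limitations

- The capped base inflates the enclosed volume by a few percent relative
  to the analytic solid and dominates the maximum surface error.
- The ICP correspondence radius is a free parameter; with a poor initial
  alignment and a small radius the method reports no-overlap rather than
  attempting a coarse search (feature-based coarse registration is out of
  scope).
- Mask-based metrics assume equal raster shapes; no image resampling is
  provided.
- The reconstruction smoothing slightly rounds sharp creases (e.g. the
  base rim); a screened-Poisson backend can be plugged in where fidelity
  at creases matters.
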