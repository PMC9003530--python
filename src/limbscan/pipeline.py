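"""End-to-end orchestration over a capture workspace on disk.

A capture session is a directory:

    workspace/
      manifest.json                    # camera order, seeds, config
      calib/intrinsics_<id>.json       # per-camera pinhole parameters
      calib/corners_<id>.json          # 3-D checkerboard corner sets
      calib/extrinsics.json            # per-camera 4×4 into the reference frame
      frames/<id>/color.png|depth.png  # aligned RGB-D rasters
      frames/<id>/silhouette.png       # ground-truth mask (simulated sessions)
      masks/<id>.png                   # segmentation output
      clouds/<id>.ply, clouds/fused.ply
      mesh/reconstruction.ply|.obj, mesh/ground_truth.ply (simulated)
      report/evaluation.json|.csv

The stages — calibrate, segment, convert to clouds, register, mesh,
evaluate — read only files, so a session can be re-run from any completed
stage and, with fixed seeds, reproduces its outputs byte for byte.  The
camera order is explicit in the manifest and drives the registration
order, mirroring how the cameras sit on the physical frame.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as lio
from .calibration import (RigidTransform, calibrate_rig, checkerboard_model,
                          load_extrinsics, save_extrinsics)
from .errors import ConfigurationError, MissingInputError
from .geometry import CameraIntrinsics, PointCloud, RGBDFrame, deproject
from .meshing import TriangleMesh, close_mesh, mesh_volume, reconstruct_surface
from .metrics import dice, mesh_distances, summary_stats, write_report
from .registration import (ICPParams, estimate_normals, pairwise_register,
                           voxel_downsample)
from .segmentation import SegmentationConfig, segment
from .synthetic import (LimbPhantom, RigLayout, add_depth_noise,
                        ground_truth_mesh, make_rig, render_checkerboard,
                        render_rgbd)

log = logging.getLogger("limbscan")

__all__ = ["CaptureSession", "simulate_session", "run_pipeline"]


@dataclass
class CaptureSession:
    """Handle on a capture workspace directory."""

    workspace: Path
    camera_ids: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        self.workspace = Path(self.workspace)

    # -- manifest ------------------------------------------------------------

    @property
    def manifest_path(self) -> Path:
        return self.workspace / "manifest.json"

    def save_manifest(self) -> None:
        self.manifest_path.parent.mkdir(parents=True, exist_ok=True)
        data = {"camera_order": self.camera_ids, "config": self.config}
        self.manifest_path.write_text(json.dumps(data, indent=2,
                                                 sort_keys=True) + "\n")

    @classmethod
    def load(cls, workspace: str | Path) -> "CaptureSession":
        workspace = Path(workspace)
        path = workspace / "manifest.json"
        if not path.exists():
            raise MissingInputError(f"no manifest.json in {workspace}")
        data = json.loads(path.read_text())
        return cls(workspace=workspace, camera_ids=list(data["camera_order"]),
                   config=dict(data.get("config", {})))

    # -- paths ---------------------------------------------------------------

    def intrinsics_path(self, cid: str) -> Path:
        return self.workspace / "calib" / f"intrinsics_{cid}.json"

    def corners_path(self, cid: str) -> Path:
        return self.workspace / "calib" / f"corners_{cid}.json"

    @property
    def extrinsics_path(self) -> Path:
        return self.workspace / "calib" / "extrinsics.json"

    def frame_dir(self, cid: str) -> Path:
        return self.workspace / "frames" / cid

    def mask_path(self, cid: str) -> Path:
        return self.workspace / "masks" / f"{cid}.png"

    def cloud_path(self, cid: str) -> Path:
        return self.workspace / "clouds" / f"{cid}.ply"

    def load_frame(self, cid: str) -> RGBDFrame:
        d = self.frame_dir(cid)
        if not (d / "color.png").exists() or not (d / "depth.png").exists():
            raise MissingInputError(f"missing color/depth for camera {cid}")
        return RGBDFrame(
            color=lio.read_color_png(d / "color.png"),
            depth=lio.read_depth_png(d / "depth.png"),
            intrinsics=CameraIntrinsics.load_json(self.intrinsics_path(cid)),
        )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def simulate_session(workspace: str | Path, seed: int = 0,
                     layout: RigLayout = RigLayout(),
                     phantom: LimbPhantom = LimbPhantom(),
                     depth_noise: float = 0.0,
                     corner_noise_mm: float = 0.0,
                     board_square_mm: float = 25.0) -> CaptureSession:
    """Emit a complete synthetic capture directory for the rig.

    Renders color/depth/silhouette per camera, writes ground-truth
    intrinsics and extrinsics, checkerboard corner observations (for the
    calibration stage), and the ground-truth phantom mesh.  ``depth_noise``
    is the relative depth accuracy at 2 m (0 disables noise).
    """
    ws = Path(workspace)
    session = CaptureSession(
        workspace=ws,
        camera_ids=[f"cam{i}" for i in range(layout.n_cameras)],
        config={
            "seed": seed,
            "depth_noise": depth_noise,
            "corner_noise_mm": corner_noise_mm,
            "board_square_mm": board_square_mm,
            "frame_radius_mm": layout.frame_radius_mm,
            "image_size": [layout.width_px, layout.height_px],
        },
    )
    poses = make_rig(layout)
    K = layout.intrinsics
    (ws / "calib").mkdir(parents=True, exist_ok=True)
    for i, cid in enumerate(session.camera_ids):
        log.info("simulate: rendering %s", cid)
        frame, silhouette = render_rgbd(phantom, poses[i], K)
        if depth_noise > 0:
            frame = add_depth_noise(frame, depth_noise, seed=seed * 1009 + i)
        d = session.frame_dir(cid)
        d.mkdir(parents=True, exist_ok=True)
        lio.write_color_png(d / "color.png", frame.color)
        lio.write_depth_png(d / "depth.png", frame.depth_mm)
        lio.write_mask_png(d / "silhouette.png", silhouette)
        K.save_json(session.intrinsics_path(cid))

    # checkerboard floating above the phantom base, tilted; every camera
    # (including the end camera) has all corners in front of it
    board_pose = RigidTransform(
        _rotation_xyz(0.3, 0.2, 0.1),
        np.array([-60.0, -70.0, phantom.base_z + 40.0]),
    )
    corner_sets = render_checkerboard(
        board_pose, poses, square_mm=board_square_mm,
        noise_sigma_mm=corner_noise_mm, seed=seed * 2003 + 17)
    for cid, corners in zip(session.camera_ids, corner_sets):
        session.corners_path(cid).write_text(
            json.dumps(corners.round(9).tolist()) + "\n")
    save_extrinsics(ws / "calib" / "extrinsics_ground_truth.json",
                    [poses[0].inverse() @ p for p in poses],
                    session.camera_ids, session.camera_ids[0])

    (ws / "mesh").mkdir(exist_ok=True)
    # the pipeline reconstructs in the reference camera's frame, so the
    # ground-truth mesh is stored in that frame too
    gt = ground_truth_mesh(phantom)
    gt = TriangleMesh(poses[0].inverse().apply(gt.vertices), gt.faces)
    gt.save(ws / "mesh" / "ground_truth.ply")
    session.save_manifest()
    return session


def _rotation_xyz(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation from intrinsic x, y, z Euler angles (radians)."""
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def stage_calibrate(session: CaptureSession,
                    board_square_mm: float | None = None) -> None:
    """Solve rig extrinsics from the stored corner observations."""
    square = board_square_mm or session.config.get("board_square_mm", 25.0)
    model = checkerboard_model(square_mm=square)
    sets = []
    for cid in session.camera_ids:
        p = session.corners_path(cid)
        if not p.exists():
            raise MissingInputError(f"calibrate: no corner set for {cid}")
        sets.append(np.array(json.loads(p.read_text())))
    transforms = calibrate_rig(sets, model, reference_camera=0)
    save_extrinsics(session.extrinsics_path, transforms, session.camera_ids,
                    session.camera_ids[0])
    log.info("calibrate: wrote %s", session.extrinsics_path)


def stage_segment(session: CaptureSession,
                  config: SegmentationConfig | None = None) -> None:
    """Segment every camera frame and store the binary masks."""
    base = config or SegmentationConfig.from_dict(
        session.config.get("segmentation", {}))
    (session.workspace / "masks").mkdir(exist_ok=True)
    for cid in session.camera_ids:
        frame = session.load_frame(cid)
        # filter sizes are defined at the sensor's native 1280-px width
        cfg = base if config else base.scaled_to(frame.intrinsics.width_px)
        mask, _ = segment(frame, cfg)
        lio.write_mask_png(session.mask_path(cid), mask)
        log.info("segment: %s → %d px", cid, int(mask.sum()))


def stage_clouds(session: CaptureSession, voxel_size_mm: float = 2.0,
                 normals_k: int = 20) -> None:
    """Deproject masked frames to per-camera clouds with normals."""
    (session.workspace / "clouds").mkdir(exist_ok=True)
    for cid in session.camera_ids:
        mp = session.mask_path(cid)
        if not mp.exists():
            raise MissingInputError(f"clouds: no mask for {cid}; run segment")
        frame = session.load_frame(cid)
        cloud = deproject(frame, lio.read_mask_png(mp))
        cloud = voxel_downsample(cloud, voxel_size_mm)
        # normals face the camera (viewpoint = camera origin), i.e. outward
        # from the scanned surface
        cloud = estimate_normals(cloud, k=min(normals_k, len(cloud) - 1),
                                 viewpoint=(0.0, 0.0, 0.0))
        lio.write_ply(session.cloud_path(cid), cloud)
        log.info("clouds: %s → %d points", cid, len(cloud))


def stage_register(session: CaptureSession,
                   params: ICPParams = ICPParams(),
                   use_ground_truth_extrinsics: bool = False) -> PointCloud:
    """Globally align and pairwise-refine the per-camera clouds."""
    ext_path = (session.workspace / "calib" / "extrinsics_ground_truth.json"
                if use_ground_truth_extrinsics else session.extrinsics_path)
    if not ext_path.exists():
        raise MissingInputError(f"register: no extrinsics at {ext_path}")
    extrinsics, _ = load_extrinsics(ext_path)
    clouds, transforms = [], []
    for cid in session.camera_ids:
        if cid not in extrinsics:
            raise ConfigurationError(f"register: unknown camera id {cid}")
        cp = session.cloud_path(cid)
        if not cp.exists():
            raise MissingInputError(f"register: no cloud for {cid}")
        clouds.append(lio.read_ply(cp))
        transforms.append(extrinsics[cid])
    fused, _ = pairwise_register(clouds, transforms, params)
    lio.write_ply(session.workspace / "clouds" / "fused.ply", fused)
    log.info("register: fused cloud has %d points", len(fused))
    return fused


def stage_mesh(session: CaptureSession, grid_resolution: int = 128
               ) -> TriangleMesh:
    """Reconstruct a watertight surface from the fused cloud."""
    fp = session.workspace / "clouds" / "fused.ply"
    if not fp.exists():
        raise MissingInputError("mesh: no fused cloud; run register")
    fused = lio.read_ply(fp)
    if fused.normals is None:
        fused = estimate_normals(fused, k=min(20, len(fused) - 1),
                                 viewpoint=fused.points.mean(axis=0))
    mesh = close_mesh(reconstruct_surface(fused, grid_resolution))
    out = session.workspace / "mesh"
    out.mkdir(exist_ok=True)
    mesh.save(out / "reconstruction.ply")
    mesh.save(out / "reconstruction.obj")
    log.info("mesh: %d vertices, watertight=%s, volume=%.0f mm³",
             len(mesh.vertices), mesh.is_watertight, mesh_volume(mesh))
    return mesh


def stage_evaluate(session: CaptureSession, n_samples: int = 100_000,
                   seed: int = 0) -> dict:
    """Compare outputs against the stored ground truth, if present.

    Produces a report with per-camera segmentation Dice scores (vs the
    simulator's silhouettes) and the summary-statistics row of
    mesh-to-ground-truth surface distances.
    """
    report: dict = {}
    rows = {}
    for cid in session.camera_ids:
        sp = session.frame_dir(cid) / "silhouette.png"
        mp = session.mask_path(cid)
        if sp.exists() and mp.exists():
            report.setdefault("segmentation_dice", {})[cid] = dice(
                lio.read_mask_png(mp), lio.read_mask_png(sp))
    mesh_p = session.workspace / "mesh" / "reconstruction.ply"
    gt_p = session.workspace / "mesh" / "ground_truth.ply"
    if mesh_p.exists() and gt_p.exists():
        mesh = TriangleMesh.load(mesh_p)
        gt = TriangleMesh.load(gt_p)
        d_ab, d_ba = mesh_distances(mesh, gt, n_samples=n_samples, seed=seed)
        stats = summary_stats(np.concatenate([d_ab, d_ba]))
        rows["mesh_vs_ground_truth_mm"] = stats
        report["mesh_vs_ground_truth_mm"] = stats.to_dict()
        report["mesh_watertight"] = bool(mesh.is_watertight)
        report["mesh_volume_mm3"] = (mesh_volume(mesh)
                                     if mesh.is_watertight else None)
    out = session.workspace / "report"
    out.mkdir(exist_ok=True)
    (out / "evaluation.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    if rows:
        write_report(out / "summary.json", rows, out / "summary.csv")
    log.info("evaluate: report written to %s", out)
    return report


def run_pipeline(session: CaptureSession,
                 seg_config: SegmentationConfig | None = None,
                 icp_params: ICPParams = ICPParams(),
                 grid_resolution: int = 128,
                 use_ground_truth_extrinsics: bool = False,
                 eval_samples: int = 100_000, seed: int = 0
                 ) -> tuple[TriangleMesh, dict]:
    """Full flow: calibrate → segment → clouds → register → mesh → evaluate.

    Returns the final watertight mesh and the evaluation report.  Stage
    errors propagate with the stage and camera named in the message.
    """
    if not use_ground_truth_extrinsics:
        stage_calibrate(session)
    stage_segment(session, seg_config)
    stage_clouds(session, voxel_size_mm=icp_params.voxel_size_mm)
    stage_register(session, icp_params,
                   use_ground_truth_extrinsics=use_ground_truth_extrinsics)
    mesh = stage_mesh(session, grid_resolution)
    report = stage_evaluate(session, n_samples=eval_samples, seed=seed)
    return mesh, report
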