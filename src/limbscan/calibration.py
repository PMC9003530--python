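"""Rigid alignment by the Kabsch algorithm and multi-camera extrinsic
calibration.

The Kabsch algorithm is the closed-form SVD solution for the rotation that
superimposes two matched point sets with minimum root-mean-square deviation
(RMSD).  Extrinsic calibration of the camera rig reduces to one Kabsch solve
per camera: every camera observes the same ordered set of checkerboard inner
corners in 3-D (in its own frame), each solve yields that camera's pose
relative to the board, and composing through the board gives every camera's
pose in the reference camera's frame.

The procedure, for matched sets P (reference) and Q:

1. centre both sets on their centroids;
2. form the covariance H = Pᵀ Q of the centred sets;
3. take the SVD H = V S Wᵀ;
4. set d = sign(det(W Vᵀ)) and R = W·diag(1, 1, d)·Vᵀ, which guarantees a
   proper rotation (det R = +1, never a reflection);
5. complete with the least-squares translation t = centroid(P) − R·centroid(Q).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateConfigurationError,
    IncompleteObservationError,
    InvalidArgumentError,
)

__all__ = [
    "RigidTransform",
    "CorrespondenceSet",
    "centroid",
    "rmsd",
    "kabsch",
    "calibrate_rig",
    "checkerboard_model",
    "save_extrinsics",
    "load_extrinsics",
]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion p ↦ R·p + t (rotation R, translation t in mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise InvalidArgumentError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise InvalidArgumentError("rotation must have det +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point or an N×3 array of points."""
        p = np.asarray(points, dtype=np.float64)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: first ``other``, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def as_matrix(self) -> np.ndarray:
        """4×4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "RigidTransform":
        M = np.asarray(M, dtype=np.float64).reshape(4, 4)
        return cls(M[:3, :3], M[:3, 3])


@dataclass(frozen=True)
class CorrespondenceSet:
    """Matched point sets: row k of the reference P corresponds to row k of Q."""

    P: np.ndarray
    Q: np.ndarray

    def __post_init__(self):
        P = np.asarray(self.P, dtype=np.float64)
        Q = np.asarray(self.Q, dtype=np.float64)
        if P.ndim != 2 or P.shape[1] != 3 or P.shape != Q.shape:
            raise InvalidArgumentError("P and Q must be matching N×3 arrays")
        if len(P) < 3:
            raise DegenerateConfigurationError("need at least 3 correspondences")
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "Q", Q)


def centroid(points: np.ndarray) -> np.ndarray:
    """Coordinate-wise mean of a non-empty point set."""
    p = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if p.size == 0:
        raise InvalidArgumentError("centroid of an empty point set")
    return p.mean(axis=0)


def rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Root-mean-square point-to-point deviation between matched sets."""
    P = np.atleast_2d(np.asarray(P, dtype=np.float64))
    Q = np.atleast_2d(np.asarray(Q, dtype=np.float64))
    if P.shape != Q.shape:
        raise InvalidArgumentError("point sets must have equal shapes")
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


def kabsch(corr: CorrespondenceSet) -> tuple[RigidTransform, float]:
    """Optimal rigid transform mapping Q onto P, and the residual RMSD.

    Returns the proper rotation R and translation t minimising
    RMSD(P, R·Q + t) in closed form.  The SVD sign check forces
    det(R) = +1 even when the unconstrained optimum would be a
    reflection.
    """
    P, Q = corr.P, corr.Q
    cP, cQ = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cP, Q - cQ
    if np.linalg.matrix_rank(P0, tol=1e-9) < 2:
        raise DegenerateConfigurationError("reference points are collinear")
    H = P0.T @ Q0
    V, _, Wt = np.linalg.svd(H)
    W = Wt.T
    d = np.sign(np.linalg.det(W @ V.T))
    # The textbook form R = W·diag(1,1,d)·Vᵀ acts on points stored as row
    # vectors (q ↦ q·R); as an operator on column vectors that is its
    # transpose, V·diag(1,1,d)·Wᵀ, which is what RigidTransform applies.
    R = V @ np.diag([1.0, 1.0, d]) @ W.T
    t = cP - R @ cQ
    T = RigidTransform(R, t)
    return T, rmsd(P, T.apply(Q))


def checkerboard_model(inner_rows: int = 6, inner_cols: int = 9,
                       square_mm: float = 25.0) -> np.ndarray:
    """Board-frame coordinates of the inner corners of a checkerboard.

    Corners are ordered row-major with the origin at the first inner corner;
    the board lies in its own z = 0 plane.  The default 6×9 board has 54
    corners.
    """
    jj, ii = np.meshgrid(np.arange(inner_cols), np.arange(inner_rows))
    pts = np.column_stack([
        jj.ravel() * square_mm,
        ii.ravel() * square_mm,
        np.zeros(inner_rows * inner_cols),
    ])
    return pts


def calibrate_rig(corner_sets: Sequence[np.ndarray], board_model: np.ndarray,
                  reference_camera: int = 0
                  ) -> list[RigidTransform]:
    """Per-camera extrinsics from shared checkerboard observations.

    Each camera's ordered 3-D corner observations (its own frame) are
    aligned to the board model with one Kabsch solve, giving
    camera-from-board; composing through the board yields
    reference-from-camera for every camera.  The reference camera maps to
    the identity.
    """
    board_model = np.asarray(board_model, dtype=np.float64)
    n_corners = len(board_model)
    cam_from_board: list[RigidTransform] = []
    for i, obs in enumerate(corner_sets):
        obs = np.asarray(obs, dtype=np.float64)
        if obs.shape != (n_corners, 3) or not np.all(np.isfinite(obs)):
            raise IncompleteObservationError(
                f"camera {i}: expected {n_corners} finite corner observations"
            )
        T, _ = kabsch(CorrespondenceSet(P=obs, Q=board_model))
        cam_from_board.append(T)
    if not 0 <= reference_camera < len(cam_from_board):
        raise InvalidArgumentError("reference camera index out of range")
    ref_from_board = cam_from_board[reference_camera]
    return [ref_from_board @ T.inverse() for T in cam_from_board]


def save_extrinsics(path: str | Path, transforms: Sequence[RigidTransform],
                    camera_ids: Sequence[str], reference_camera: str) -> None:
    """Persist per-camera extrinsics as 4×4 row-major matrices in JSON."""
    data = {
        "reference_camera": reference_camera,
        "cameras": {
            cid: T.as_matrix().round(12).tolist()
            for cid, T in zip(camera_ids, transforms)
        },
    }
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def load_extrinsics(path: str | Path) -> tuple[dict[str, RigidTransform], str]:
    data = json.loads(Path(path).read_text())
    cams = {
        cid: RigidTransform.from_matrix(np.array(M))
        for cid, M in data["cameras"].items()
    }
    return cams, data["reference_camera"]
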