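"""Spatial alignment: rigid mapping of the depth stream into the RGB
detector's reference frame, and pinhole projection to pixel coordinates.

The depth camera and the RGB detector observe the same skeleton in
different coordinate systems.  Calibration (intrinsics fx, fy, dx, dy,
scale s; extrinsics R, T) comes from a config file; estimating it is out
of scope.  Alignment and projection are kept as two separate, standard
operations: a rigid 3-D transform ``p -> R p + T`` into the reference
frame, and a pinhole projection ``u = fx X/Z + dx, v = fy Y/Z + dy`` used
only where evaluation needs pixel distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .keypoints import KeypointSequence


@dataclass
class CameraCalibration:
    fx: float
    fy: float
    dx: float
    dy: float
    s: float = 1.0
    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    T: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=np.float64).reshape(3, 3)
        self.T = np.asarray(self.T, dtype=np.float64).reshape(3)
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if self.s <= 0:
            raise ValueError("scale factor must be positive")
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-8):
            raise ValueError("R is not orthonormal")
        if not np.isclose(np.linalg.det(self.R), 1.0, atol=1e-8):
            raise ValueError("R must be a proper rotation (det +1)")

    @classmethod
    def from_dict(cls, d: dict) -> "CameraCalibration":
        """Build from a config mapping with keys fx, fy, dx, dy, s, R, T.

        R is 9 numbers row-major; T is 3 numbers.
        """
        return cls(
            fx=float(d["fx"]),
            fy=float(d["fy"]),
            dx=float(d["dx"]),
            dy=float(d["dy"]),
            s=float(d.get("s", 1.0)),
            R=np.asarray(d.get("R", np.eye(3).ravel()), dtype=float).reshape(3, 3),
            T=np.asarray(d.get("T", np.zeros(3)), dtype=float),
        )

    def to_dict(self) -> dict:
        return {
            "fx": self.fx, "fy": self.fy, "dx": self.dx, "dy": self.dy,
            "s": self.s, "R": self.R.ravel().tolist(), "T": self.T.tolist(),
        }

    def inverse_extrinsics(self) -> "CameraCalibration":
        """Calibration with (Rᵀ, −Rᵀ T): undoes the rigid transform."""
        return CameraCalibration(
            self.fx, self.fy, self.dx, self.dy, self.s,
            R=self.R.T, T=-self.R.T @ self.T,
        )


def transform_to_reference(seq: KeypointSequence, calib: CameraCalibration) -> KeypointSequence:
    """Rigidly map every valid joint into the reference frame: p -> R p + T."""
    if seq.unit != "m":
        raise ValueError("transform_to_reference expects a metric 3-D sequence")
    coords = seq.coords.copy()
    v = seq.valid
    coords[v] = coords[v] @ calib.R.T + calib.T
    return seq.copy(coords=coords, source="aligned")


def project_to_image(seq: KeypointSequence, calib: CameraCalibration) -> KeypointSequence:
    """Pinhole-project valid 3-D joints to 2-D pixels.

    The scale factor s is applied to the 3-D point before projection (it
    cancels in X/Z and Y/Z and is kept for completeness).  The output Z
    column is zeroed and the unit set to pixels.  Any valid joint with
    non-positive depth is an error naming the frame and joint.
    """
    if seq.unit != "m":
        raise ValueError("project_to_image expects a metric 3-D sequence")
    pts = calib.s * seq.coords
    Z = pts[:, :, 2]
    bad = seq.valid & (Z <= 0)
    if np.any(bad):
        i, k = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive depth at frame {int(seq.frame_index[i])}, "
            f"joint {seq.joints[k]!r}: Z = {Z[i, k]}"
        )
    out = np.full_like(seq.coords, np.nan)
    with np.errstate(invalid="ignore"):
        out[:, :, 0] = calib.fx * pts[:, :, 0] / Z + calib.dx
        out[:, :, 1] = calib.fy * pts[:, :, 1] / Z + calib.dy
    out[:, :, 2] = 0.0
    out[~seq.valid] = np.nan
    return seq.copy(coords=out, unit="px")
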