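"""Two-sensor camera model for an RGB-D rig.

The rig holds the pinhole intrinsics of the depth and color sensors and the
rigid transform (rotation ``R``, translation ``t`` in millimetres) that maps
points from the depth-camera frame into the color-camera frame:
``X_color = R @ X_depth + t``.

Pixel convention: ``(u, v) = (column, row)``, 0-based, pixel-centre sampling.
Deprojection of pixel ``(u, v)`` at metric depth ``d`` (mm along the optical
axis) is ``X = d * K^{-1} @ (u, v, 1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["CameraRig", "intrinsics_matrix"]


def intrinsics_matrix(fx: float, fy: float, cx: float, cy: float) -> np.ndarray:
    """Build a 3x3 pinhole intrinsics matrix from focal lengths and principal point."""
    return np.array([[fx, 0.0, cx], [0.0, fy, cy], [0.0, 0.0, 1.0]])


@dataclass
class CameraRig:
    """Intrinsics of both sensors plus the depth-to-color extrinsics.

    Attributes
    ----------
    K_depth, K_color:
        3x3 intrinsic matrices (fx, fy, cx, cy in pixels).
    R:
        3x3 rotation, depth frame to color frame; orthonormal, det = +1.
    t:
        3-vector translation in mm, depth frame to color frame.
    """

    K_depth: np.ndarray
    K_color: np.ndarray
    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.K_depth = np.asarray(self.K_depth, dtype=float).reshape(3, 3)
        self.K_color = np.asarray(self.K_color, dtype=float).reshape(3, 3)
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        for name, K in (("K_depth", self.K_depth), ("K_color", self.K_color)):
            if K[0, 0] <= 0 or K[1, 1] <= 0:
                raise ValueError(f"{name}: focal lengths must be positive")
            if abs(np.linalg.det(K)) < 1e-12:
                raise ValueError(f"{name}: intrinsics matrix is singular")
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-6):
            raise ValueError("R must be orthonormal")
        if np.linalg.det(self.R) < 0:
            raise ValueError("R must be a proper rotation (det = +1)")

    @classmethod
    def identity(cls, fx: float, fy: float, cx: float, cy: float) -> "CameraRig":
        """Rig whose two sensors coincide (same intrinsics, R = I, t = 0)."""
        K = intrinsics_matrix(fx, fy, cx, cy)
        return cls(K_depth=K, K_color=K.copy())

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        def cam(K: np.ndarray) -> dict:
            return {
                "fx": float(K[0, 0]),
                "fy": float(K[1, 1]),
                "cx": float(K[0, 2]),
                "cy": float(K[1, 2]),
            }

        return {
            "depth": cam(self.K_depth),
            "color": cam(self.K_color),
            "R": [[float(v) for v in row] for row in self.R],
            "t_mm": [float(v) for v in self.t],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraRig":
        def mat(c: dict) -> np.ndarray:
            return intrinsics_matrix(c["fx"], c["fy"], c["cx"], c["cy"])

        return cls(
            K_depth=mat(d["depth"]),
            K_color=mat(d["color"]),
            R=np.asarray(d.get("R", np.eye(3).tolist()), dtype=float),
            t=np.asarray(d.get("t_mm", [0.0, 0.0, 0.0]), dtype=float),
        )

    def save(self, path: str | Path) -> None:
        """Write the rig as YAML (or JSON if the suffix is .json)."""
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "CameraRig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)

    # -- geometry -----------------------------------------------------------

    def deproject_depth(self, u: np.ndarray, v: np.ndarray, d: np.ndarray) -> np.ndarray:
        """Depth pixels (u, v) at metric depth d -> (N, 3) points, depth frame."""
        Kinv = np.linalg.inv(self.K_depth)
        pix = np.stack([u, v, np.ones_like(u, dtype=float)], axis=0)
        return (d * (Kinv @ pix)).T

    def project_color(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(N, 3) points in the color frame -> pixel (u, v) and depth z."""
        z = points[:, 2]
        proj = (self.K_color @ points.T).T
        with np.errstate(divide="ignore", invalid="ignore"):
            u = proj[:, 0] / z
            v = proj[:, 1] / z
        return u, v, z

    def depth_to_color_frame(self, points: np.ndarray) -> np.ndarray:
        """Transform (N, 3) points from the depth frame into the color frame."""
        return points @ self.R.T + self.t
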