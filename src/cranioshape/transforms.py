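"""Similarity transforms (isotropic scale + rotation + translation).

A :class:`SimilarityTransform` maps physical points ``p`` (mm) of its
``target_grid`` — the reference space a volume is being warped *onto* — into
the physical space of the source volume being resampled::

    T(p) = scale * R @ (p - center) + center + translation

This is the resampling (pull-back) convention used by ITK: to warp a moving
volume onto a fixed grid, the transform carries fixed-grid points into the
moving volume, where values are interpolated. The inverse transform has a
closed form and swaps the roles of the two spaces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy.spatial.transform import Rotation

from .volume import GridSpec


@dataclass
class SimilarityTransform:
    """7-parameter similarity map: scale, rotation, translation about a center."""

    scale: float
    rotation: np.ndarray  # 3x3 rotation matrix
    translation: np.ndarray  # (3,) mm
    center: np.ndarray  # (3,) mm, fixed point of rotation/scaling
    target_grid: GridSpec
    converged: bool = True

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.scale = float(self.scale)
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be an orthogonal matrix")

    # -- constructors ------------------------------------------------------

    @classmethod
    def identity(cls, target_grid: GridSpec) -> "SimilarityTransform":
        return cls(1.0, np.eye(3), np.zeros(3), np.zeros(3), target_grid)

    @classmethod
    def from_params(
        cls,
        scale: float,
        angles_rad: tuple[float, float, float],
        translation,
        center,
        target_grid: GridSpec,
    ) -> "SimilarityTransform":
        """Build from scale, intrinsic x-y-z Euler angles and translation."""
        R = Rotation.from_euler("xyz", angles_rad).as_matrix()
        return cls(scale, R, np.asarray(translation, float), np.asarray(center, float), target_grid)

    # -- derived parameters ------------------------------------------------

    @property
    def euler_angles(self) -> np.ndarray:
        """Rotation as intrinsic x-y-z Euler angles in radians."""
        return Rotation.from_matrix(self.rotation).as_euler("xyz")

    @property
    def rotation_angle(self) -> float:
        """Total rotation angle (radians) about the rotation axis."""
        return float(Rotation.from_matrix(self.rotation).magnitude())

    # -- geometry ----------------------------------------------------------

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) or (3,) physical points through the transform."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = self.scale * (p - self.center) @ self.rotation.T + self.center + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def invert(self, original_grid: GridSpec) -> "SimilarityTransform":
        """The inverse map; ``original_grid`` becomes the new target grid.

        With T(p) = s R (p - c) + c + t, the inverse about the same center is
        scale 1/s, rotation R^T and translation -(1/s) R^T t.
        """
        s_inv = 1.0 / self.scale
        R_inv = self.rotation.T
        t_inv = -s_inv * (R_inv @ self.translation)
        return SimilarityTransform(
            s_inv, R_inv, t_inv, self.center.copy(), original_grid, self.converged
        )

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """The map ``p -> self(other(p))``; keeps ``other``'s target grid."""
        s = self.scale * other.scale
        R = self.rotation @ other.rotation
        t = (
            self.scale * self.rotation @ (other.center + other.translation - self.center)
            + self.center
            + self.translation
            - other.center
        )
        return SimilarityTransform(
            s, R, t, other.center.copy(), other.target_grid,
            self.converged and other.converged,
        )

    def is_identity(
        self, scale_tol: float = 1e-6, angle_tol: float = 1e-6, trans_tol: float = 1e-6
    ) -> bool:
        return (
            abs(self.scale - 1.0) <= scale_tol
            and self.rotation_angle <= angle_tol
            and np.abs(self.translation).max() <= trans_tol
        )

    # -- SimpleITK interop -------------------------------------------------

    def to_sitk(self) -> sitk.Similarity3DTransform:
        tx = sitk.Similarity3DTransform()
        tx.SetCenter(tuple(self.center))
        tx.SetMatrix(tuple((self.scale * self.rotation).flatten()), 1e-8)
        tx.SetTranslation(tuple(self.translation))
        return tx

    @classmethod
    def from_sitk(
        cls, tx: sitk.Similarity3DTransform, target_grid: GridSpec, converged: bool = True
    ) -> "SimilarityTransform":
        scale = float(tx.GetScale())
        R = np.asarray(tx.GetMatrix()).reshape(3, 3) / scale
        return cls(
            scale, R, np.asarray(tx.GetTranslation()), np.asarray(tx.GetCenter()),
            target_grid, converged,
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "center": self.center.tolist(),
            "target_grid": {
                "shape": list(self.target_grid.shape),
                "spacing": list(self.target_grid.spacing),
                "origin": list(self.target_grid.origin),
            },
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        g = d["target_grid"]
        grid = GridSpec(tuple(g["shape"]), tuple(g["spacing"]), tuple(g["origin"]))
        return cls(
            d["scale"], np.asarray(d["rotation"]), np.asarray(d["translation"]),
            np.asarray(d["center"]), grid, d.get("converged", True),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SimilarityTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))
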