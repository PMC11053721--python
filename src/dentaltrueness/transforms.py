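"""Rigid transforms (rotation + translation) in millimetres."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform"]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R x + t``.

    ``rotation`` must be orthonormal with determinant +1 (checked to 1e-9);
    ``translation`` is in mm.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation is not orthonormal (tol 1e-9)")
        if not np.isclose(np.linalg.det(R), 1.0, atol=_ORTHO_TOL):
            raise ValueError("rotation must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors ------------------------------------------------------

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        m = np.asarray(matrix, dtype=np.float64).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    @classmethod
    def from_rotation(cls, rotation, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from a possibly slightly non-orthonormal matrix.

        The rotation is projected onto SO(3) via SVD; useful for composing
        incremental ICP updates without drift.
        """
        R = np.asarray(rotation, dtype=np.float64).reshape(3, 3)
        u, _, vt = np.linalg.svd(R)
        R = u @ vt
        if np.linalg.det(R) < 0:
            u[:, -1] *= -1
            R = u @ vt
        return cls(R, np.asarray(translation, dtype=np.float64))

    @classmethod
    def from_axis_angle(
        cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0), center=None
    ) -> "RigidTransform":
        """Rotation by ``angle_deg`` about ``axis``; optionally about ``center``."""
        axis = np.asarray(axis, dtype=np.float64)
        axis = axis / np.linalg.norm(axis)
        a = np.deg2rad(angle_deg)
        K = np.array(
            [
                [0, -axis[2], axis[1]],
                [axis[2], 0, -axis[0]],
                [-axis[1], axis[0], 0],
            ]
        )
        R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
        t = np.asarray(translation, dtype=np.float64)
        if center is not None:
            c = np.asarray(center, dtype=np.float64)
            t = t + c - R @ c
        return cls.from_rotation(R, t)

    # -- operations --------------------------------------------------------

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (used for report serialization)."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
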