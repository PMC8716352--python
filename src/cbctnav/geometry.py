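"""Rigid transforms in 3-D world coordinates.

All world coordinates in this package are LPS (Left-Posterior-Superior,
the DICOM patient convention) in millimetres.  A :class:`RigidTransform`
is a proper rotation plus a translation; reflections are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform"]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R x + t``.

    Parameters
    ----------
    rotation
        3x3 orthonormal matrix with det = +1.
    translation
        3-vector, millimetres.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix has det = -1 (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix (row-major)."""
        M = np.asarray(matrix, dtype=float).reshape(4, 4)
        return cls(M[:3, :3], M[:3, 3])

    def as_matrix(self) -> np.ndarray:
        """Return the 4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point (3,) or a stack of points (n, 3)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_vector(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        v = np.asarray(vectors, dtype=float)
        return v @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    @classmethod
    def from_euler_deg(
        cls, rx: float = 0.0, ry: float = 0.0, rz: float = 0.0,
        translation: np.ndarray | None = None,
    ) -> "RigidTransform":
        """Intrinsic x-y-z Euler rotation (degrees) plus translation."""
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [rx, ry, rz], degrees=True).as_matrix()
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return cls(R, t)

    @classmethod
    def random(cls, rng: np.random.Generator,
               max_rotation_deg: float = 30.0,
               max_translation_mm: float = 40.0) -> "RigidTransform":
        """Uniform random axis, rotation angle and translation within bounds."""
        from scipy.spatial.transform import Rotation

        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0.0, np.radians(max_rotation_deg))
        R = Rotation.from_rotvec(axis * angle).as_matrix()
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        t = direction * rng.uniform(0.0, max_translation_mm)
        return cls(R, t)
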