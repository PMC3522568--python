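"""Rigid-body transforms for docking poses.

A pose of the mobile partner (the ligand) is a proper rigid motion
``x -> R x + t`` with the rotation stored as a unit quaternion.  Scalar-last
(x, y, z, w) component order is used throughout, matching
:class:`scipy.spatial.transform.Rotation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform"]

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A rotation-then-translation rigid motion in 3-space.

    Parameters
    ----------
    quaternion
        Unit quaternion, scalar-last ``(x, y, z, w)``.  Normalized on
        construction; a zero quaternion is rejected.
    translation
        Translation vector in Angstrom, applied after the rotation.
    """

    quaternion: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0])
    )
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        q = np.asarray(self.quaternion, dtype=float).reshape(4)
        norm = float(np.linalg.norm(q))
        if not np.isfinite(norm) or norm == 0.0:
            raise ValueError("quaternion must be non-zero and finite")
        q = q / norm
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise ValueError("translation must be finite")
        object.__setattr__(self, "quaternion", q)
        object.__setattr__(self, "translation", t)

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_rotation(
        cls, rotation: Rotation, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        return cls(rotation.as_quat(), np.asarray(translation, dtype=float))

    @classmethod
    def from_rotvec(cls, rotvec, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls.from_rotation(Rotation.from_rotvec(rotvec), translation)

    # -- accessors ----------------------------------------------------
    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.quaternion)

    def matrix(self) -> np.ndarray:
        return self.rotation.as_matrix()

    # -- algebra ------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array (or a single 3-vector) of coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix().T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        r = self.rotation * other.rotation
        t = self.rotation.apply(other.translation) + self.translation
        return RigidTransform(r.as_quat(), t)

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.inv()
        return RigidTransform(rinv.as_quat(), -rinv.apply(self.translation))

    def rotation_angle_to(self, other: "RigidTransform") -> float:
        """Relative rotation angle (radians) between two transforms."""
        rel = self.rotation.inv() * other.rotation
        return float(rel.magnitude())

    def is_unit(self, tol: float = _UNIT_TOL) -> bool:
        return abs(float(np.linalg.norm(self.quaternion)) - 1.0) <= tol
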