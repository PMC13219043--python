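"""SE(3)/SO(3) primitives and the point-cloud container.

Conventions used throughout the package:

* column-vector action ``p' = R @ p + T`` (points stored as row-major
  ``(N, 3)`` arrays, so the vectorised form is ``points @ R.T + T``);
* coordinates in millimetres, angles in radians internally (degrees only
  at reporting boundaries);
* normals are direction vectors and transform by rotation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InvalidTransformError

#: Frobenius tolerance for SO(3) membership checks.
SO3_TOL = 1e-9

#: Tolerance for unit-normal validation.
NORMAL_TOL = 1e-6


def _as_array(x, shape, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != shape:
        raise InvalidTransformError(f"{name} must have shape {shape}, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InvalidTransformError(f"{name} contains non-finite values")
    return a


def is_rotation(R: np.ndarray, tol: float = SO3_TOL) -> bool:
    """True if ``R`` is orthonormal with determinant +1 within ``tol``."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.all(np.isfinite(R)):
        return False
    if np.linalg.norm(R.T @ R - np.eye(3)) > tol:
        return False
    return abs(np.linalg.det(R) - 1.0) <= tol


def orthonormalize(R: np.ndarray) -> np.ndarray:
    """Project a near-rotation onto SO(3) via SVD (explicit utility; inputs
    failing the SO(3) tolerance are otherwise rejected, never silently fixed)."""
    U, _, Vt = np.linalg.svd(np.asarray(R, dtype=float))
    D = np.diag([1.0, 1.0, np.linalg.det(U @ Vt)])
    return U @ D @ Vt


@dataclass(frozen=True)
class RigidTransform:
    """A rigid motion of 3-space: rotation ``R`` (3x3) and translation ``T`` (mm)."""

    R: np.ndarray
    T: np.ndarray

    def __post_init__(self):
        R = _as_array(self.R, (3, 3), "R")
        T = _as_array(self.T, (3,), "T")
        if not is_rotation(R):
            raise InvalidTransformError(
                "R is not a rotation matrix (orthonormality/det within 1e-9 required)"
            )
        R.setflags(write=False)
        T.setflags(write=False)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "T", T)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map ``(N, 3)`` (or ``(3,)``) points through ``R p + T``."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.R.T + self.T

    def apply_directions(self, vecs: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (translation-invariant)."""
        return np.asarray(vecs, dtype=float) @ self.R.T

    # -- serialization views -------------------------------------------------
    def as_matrix(self) -> np.ndarray:
        """Homogeneous 4x4 row-major view (serialization only)."""
        M = np.eye(4)
        M[:3, :3] = self.R
        M[:3, 3] = self.T
        return M

    @classmethod
    def from_matrix(cls, M) -> "RigidTransform":
        M = _as_array(M, (4, 4), "homogeneous matrix")
        if not np.allclose(M[3], [0, 0, 0, 1], atol=1e-12):
            raise InvalidTransformError("last row of a homogeneous matrix must be [0,0,0,1]")
        return cls(M[:3, :3], M[:3, 3])

    def to_dict(self) -> dict:
        return {
            "rotation": [float(v) for v in self.R.ravel()],
            "translation": [float(v) for v in self.T],
            "units": "mm",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        R = np.asarray(d["rotation"], dtype=float).reshape(3, 3)
        return cls(R, np.asarray(d["translation"], dtype=float))


@dataclass(frozen=True)
class RotationIncrement:
    """Small-motion update ``xi = [omega, dt]``: rotation vector (rad) and
    translation increment (mm) solved from one linearized point-to-plane pass."""

    omega: np.ndarray
    dt: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "omega", _as_array(self.omega, (3,), "omega"))
        object.__setattr__(self, "dt", _as_array(self.dt, (3,), "dt"))

    def as_transform(self) -> RigidTransform:
        return RigidTransform(exp_so3(self.omega), self.dt)

    @property
    def angle(self) -> float:
        return float(np.linalg.norm(self.omega))


@dataclass(frozen=True)
class PointCloud:
    """``(N, 3)`` coordinates in mm with optional unit normals."""

    points: np.ndarray
    normals: Optional[np.ndarray] = field(default=None)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite values")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)
        if self.normals is not None:
            nrm = np.asarray(self.normals, dtype=float)
            if nrm.shape != pts.shape:
                raise ValueError("normals must match points in shape")
            if not np.all(np.isfinite(nrm)):
                raise ValueError("normals contain non-finite values")
            lens = np.linalg.norm(nrm, axis=1)
            if np.any(np.abs(lens - 1.0) > NORMAL_TOL):
                raise ValueError("normals must be unit length within 1e-6")
            nrm.setflags(write=False)
            object.__setattr__(self, "normals", nrm)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def has_normals(self) -> bool:
        return self.normals is not None

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def bounding_radius(self) -> float:
        """Radius of the smallest centroid-centred sphere containing the cloud."""
        return float(np.linalg.norm(self.points - self.centroid(), axis=1).max())


# ---------------------------------------------------------------------------
# transform algebra
# ---------------------------------------------------------------------------

def compose(A: RigidTransform, B: RigidTransform) -> RigidTransform:
    """``compose(A, B)`` maps ``p -> A(B(p))``."""
    return RigidTransform(A.R @ B.R, A.R @ B.T + A.T)


def invert(A: RigidTransform) -> RigidTransform:
    return RigidTransform(A.R.T, -A.R.T @ A.T)


def apply_transform(A: RigidTransform, cloud: PointCloud) -> PointCloud:
    """Move a cloud rigidly; normals (if any) rotate with it."""
    normals = A.apply_directions(cloud.normals) if cloud.has_normals else None
    return PointCloud(A.apply(cloud.points), normals)


def skew(omega: np.ndarray) -> np.ndarray:
    """The cross-product matrix ``[omega]x`` with ``[omega]x v = omega x v``."""
    wx, wy, wz = np.asarray(omega, dtype=float)
    return np.array([[0.0, -wz, wy], [wz, 0.0, -wx], [-wy, wx, 0.0]])


def exp_so3(omega) -> np.ndarray:
    """Exponential map so(3) -> SO(3) (Rodrigues formula via scipy)."""
    omega = _as_array(omega, (3,), "omega")
    return Rotation.from_rotvec(omega).as_matrix()


def rotation_angle(R: np.ndarray) -> float:
    """Rotation angle of ``R`` in radians, ``arccos((trace-1)/2)`` clamped to [0, pi]."""
    R = np.asarray(R, dtype=float)
    if not is_rotation(R, tol=1e-8):
        raise InvalidTransformError("rotation_angle requires an SO(3) input")
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.arccos(np.clip(c, -1.0, 1.0)))
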