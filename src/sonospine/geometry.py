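"""Coordinate systems, poses and rigid transforms.

A tracked-ultrasound setup involves four frames: the raw B-mode image
plane (``p``), the position sensor mounted on the probe (``r``, receiver),
the electromagnetic transmitter (``t``), and the user-chosen reconstruction
frame (``c``).  A pixel of a B-mode frame reaches world (reconstruction)
coordinates through the chain

    c_T_p = c_T_t . t_T_r . r_T_p

where ``t_T_r`` is streamed by the tracker, ``r_T_p`` comes from spatial
calibration, and ``c_T_t`` is chosen by the user (identity by default).

Conventions
-----------
* 6-DOF poses carry translations in millimetres and intrinsic Z-Y-X Euler
  angles (azimuth ``alpha`` about z, elevation ``beta`` about y, roll
  ``gamma`` about x) in degrees; matrices are used internally.
* Image pixel (u, v) = (column, row); u runs laterally along the
  transducer array, v runs into the tissue (depth); pixel (0, 0) sits at
  a probe-face corner; the image plane is z = 0 in probe coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Pose",
    "RigidTransform",
    "FrameGeometry",
    "InvalidPoseError",
    "pose_to_matrix",
    "matrix_to_pose",
    "compose_chain",
    "map_pixel_to_world",
]

# Intrinsic rotations use upper-case axis labels in scipy.
_EULER_ORDER = "ZYX"
EULER_CONVENTION = "intrinsic-ZYX(alpha,beta,gamma)"

_ORTHO_TOL = 1e-9


class InvalidPoseError(ValueError):
    """Raised when a pose contains non-finite parameters."""


@dataclass(frozen=True)
class Pose:
    """A 6-DOF rigid pose: translations in mm, Euler angles in degrees."""

    tx: float
    ty: float
    tz: float
    alpha: float
    beta: float
    gamma: float
    timestamp: Optional[float] = None

    def __post_init__(self) -> None:
        vals = (self.tx, self.ty, self.tz, self.alpha, self.beta, self.gamma)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidPoseError(f"pose parameters must be finite, got {vals}")

    def params(self) -> np.ndarray:
        return np.array(
            [self.tx, self.ty, self.tz, self.alpha, self.beta, self.gamma],
            dtype=float,
        )


class RigidTransform:
    """A 4x4 homogeneous rigid-body transform.

    The rotation block is proper-orthonormal (det = +1 within 1e-9) and the
    last row is (0, 0, 0, 1).  Compose with ``@``; apply to points with
    :meth:`apply`.
    """

    __slots__ = ("matrix",)

    def __init__(self, matrix: np.ndarray, *, validate: bool = True):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got shape {m.shape}")
        if validate:
            _validate_rigid(m)
        self.matrix = m

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4), validate=False)

    @classmethod
    def from_pose(cls, pose: Pose) -> "RigidTransform":
        return pose_to_matrix(pose)

    @classmethod
    def from_rotation_translation(
        cls, rotation: np.ndarray, translation: Sequence[float]
    ) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return cls(m)

    # -- algebra ------------------------------------------------------
    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.matrix @ other.matrix, validate=False)

    def inverse(self) -> "RigidTransform":
        r = self.matrix[:3, :3]
        t = self.matrix[:3, 3]
        inv = np.eye(4)
        inv[:3, :3] = r.T
        inv[:3, 3] = -r.T @ t
        return RigidTransform(inv, validate=False)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform (3,) or (n, 3) point arrays (mm)."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = p @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if single else out

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def to_pose(self) -> Pose:
        return matrix_to_pose(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RigidTransform(\n{np.array_str(self.matrix, precision=6)}\n)"


def _validate_rigid(m: np.ndarray) -> None:
    if not np.all(np.isfinite(m)):
        raise ValueError("transform contains non-finite entries")
    if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=_ORTHO_TOL):
        raise ValueError("last row of a homogeneous rigid transform must be (0,0,0,1)")
    r = m[:3, :3]
    if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
        raise ValueError("rotation block is not orthonormal")
    if abs(np.linalg.det(r) - 1.0) > 1e-8:
        raise ValueError("rotation block must be a proper rotation (det = +1)")


@dataclass(frozen=True)
class FrameGeometry:
    """Pixel scaling of a B-mode frame.

    ``pixel_spacing_x`` is the lateral mm/pixel (along the transducer
    array, column direction), ``pixel_spacing_y`` the axial mm/pixel
    (depth, row direction).  ``width``/``height`` are columns/rows.
    """

    pixel_spacing_x: float
    pixel_spacing_y: float
    width: int = 640
    height: int = 480

    def __post_init__(self) -> None:
        if self.pixel_spacing_x <= 0 or self.pixel_spacing_y <= 0:
            raise ValueError("pixel spacings must be positive")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame dimensions must be positive")

    @property
    def width_mm(self) -> float:
        return self.width * self.pixel_spacing_x

    @property
    def depth_mm(self) -> float:
        return self.height * self.pixel_spacing_y


def pose_to_matrix(pose: Pose) -> RigidTransform:
    """Build the homogeneous matrix of a 6-DOF pose.

    Rotation is intrinsic Z-Y-X: azimuth ``alpha`` about z, then elevation
    ``beta`` about the rotated y, then roll ``gamma`` about the rotated x.
    """
    rot = Rotation.from_euler(
        _EULER_ORDER, [pose.alpha, pose.beta, pose.gamma], degrees=True
    ).as_matrix()
    return RigidTransform.from_rotation_translation(rot, (pose.tx, pose.ty, pose.tz))


def matrix_to_pose(transform: RigidTransform) -> Pose:
    """Recover the 6-DOF pose of a rigid transform (angles in degrees).

    Inverse of :func:`pose_to_matrix` for angles in the principal Euler
    range (beta in [-90, 90]).
    """
    alpha, beta, gamma = Rotation.from_matrix(transform.rotation).as_euler(
        _EULER_ORDER, degrees=True
    )
    tx, ty, tz = transform.translation
    return Pose(tx, ty, tz, alpha, beta, gamma)


def compose_chain(
    c_T_t: RigidTransform, t_T_r: RigidTransform, r_T_p: RigidTransform
) -> RigidTransform:
    """Chain the image-to-reconstruction transform c_T_p = c_T_t . t_T_r . r_T_p."""
    return c_T_t @ t_T_r @ r_T_p


def pixel_to_probe(u, v, geom: FrameGeometry) -> np.ndarray:
    """Pixel indices -> probe-frame mm coordinates (z = 0 plane).

    Accepts scalars or arrays; returns shape (..., 3).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    pts = np.stack(
        [u * geom.pixel_spacing_x, v * geom.pixel_spacing_y, np.zeros_like(u)],
        axis=-1,
    )
    return pts


def map_pixel_to_world(
    u, v, geom: FrameGeometry, c_T_p: RigidTransform
) -> np.ndarray:
    """World (reconstruction-frame) position of pixel (u, v), in mm.

    (u, v) must lie inside the frame bounds; scalar or array inputs.
    """
    u_arr = np.asarray(u)
    v_arr = np.asarray(v)
    if np.any(u_arr < 0) or np.any(u_arr >= geom.width):
        raise IndexError(f"column index out of bounds [0, {geom.width})")
    if np.any(v_arr < 0) or np.any(v_arr >= geom.height):
        raise IndexError(f"row index out of bounds [0, {geom.height})")
    return c_T_p.apply(pixel_to_probe(u_arr, v_arr, geom))
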