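"""Cross-wire spatial calibration of the probe-to-sensor transform.

The wire crossing of a calibration phantom is imaged repeatedly from
different probe orientations.  Each observation gives the pixel (u, v)
where the wire point appears, together with the tracker pose t_T_r of that
frame.  The unknowns are the probe-to-sensor transform r_T_p (6
parameters) and the fixed wire location w in the transmitter frame (3
parameters); with x_i the wire pixel in probe-frame mm, they satisfy

    t_T_r_i . r_T_p . x_i = w        for every observation i.

The nine parameters are estimated by damped Gauss-Newton (Levenberg-
Marquardt) on the stacked 3-vector residuals, initialised at the identity
transform and the centroid of the sensor-frame pixel positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .geometry import FrameGeometry, Pose, RigidTransform, pixel_to_probe, pose_to_matrix

__all__ = [
    "CalibrationResult",
    "DegenerateGeometryError",
    "ConvergenceError",
    "calibrate_crosswire",
]

MIN_OBSERVATIONS = 8
MIN_DISTINCT_ORIENTATIONS = 3


class DegenerateGeometryError(ValueError):
    """Observation set cannot constrain the calibration (too few poses/orientations)."""


class ConvergenceError(RuntimeError):
    """The least-squares solver failed to converge."""


@dataclass(frozen=True)
class CalibrationResult:
    """Estimated probe-to-sensor transform, wire point, and fit quality."""

    probe_to_sensor: RigidTransform  # r_T_p
    wire_point: np.ndarray  # (3,) mm, transmitter frame
    residual_rms: float  # mm
    n_observations: int


def _distinct_orientations(poses: Sequence[Pose], atol_deg: float = 1e-6) -> int:
    angles = np.array([[p.alpha, p.beta, p.gamma] for p in poses], dtype=float)
    seen: list[np.ndarray] = []
    for a in angles:
        if not any(np.allclose(a, s, atol=atol_deg) for s in seen):
            seen.append(a)
    return len(seen)


def calibrate_crosswire(
    pixels: np.ndarray,
    poses: Sequence[Pose],
    geom: FrameGeometry,
) -> CalibrationResult:
    """Solve for r_T_p and the wire point from cross-wire observations.

    Parameters
    ----------
    pixels : (n, 2) array
        Wire-point pixel (u, v) per observation.
    poses : sequence of Pose
        Tracker pose t_T_r per observation (same order).
    geom : FrameGeometry
        Pixel spacings of the B-mode frames.

    Returns
    -------
    CalibrationResult with the 6-DOF probe-to-sensor transform, the
    estimated wire location (mm, transmitter frame) and the RMS of the
    per-observation point residuals (mm).

    Raises
    ------
    DegenerateGeometryError
        Fewer than 8 observations, or fewer than 3 distinct orientations.
    ConvergenceError
        Solver failure.
    """
    pix = np.asarray(pixels, dtype=float)
    if pix.ndim != 2 or pix.shape[1] != 2:
        raise ValueError("pixels must have shape (n, 2)")
    if len(poses) != len(pix):
        raise ValueError("pixels and poses must have equal length")
    if len(pix) < MIN_OBSERVATIONS:
        raise DegenerateGeometryError(
            f"need at least {MIN_OBSERVATIONS} observations, got {len(pix)}"
        )
    if _distinct_orientations(poses) < MIN_DISTINCT_ORIENTATIONS:
        raise DegenerateGeometryError(
            f"need at least {MIN_DISTINCT_ORIENTATIONS} distinct probe orientations"
        )

    # Probe-frame positions of the wire pixels, and stacked tracker matrices.
    p_probe = pixel_to_probe(pix[:, 0], pix[:, 1], geom)  # (n, 3)
    t_T_r = np.stack([pose_to_matrix(p).matrix for p in poses])  # (n, 4, 4)
    rot_tr = t_T_r[:, :3, :3]
    trans_tr = t_T_r[:, :3, 3]

    def unpack(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        rot = Rotation.from_euler("ZYX", x[3:6]).as_matrix()  # radians internally
        return x[:3], rot, x[6:9]

    def residuals(x: np.ndarray) -> np.ndarray:
        t_rp, r_rp, wire = unpack(x)
        sensor_pts = p_probe @ r_rp.T + t_rp  # r-frame
        world_pts = np.einsum("nij,nj->ni", rot_tr, sensor_pts) + trans_tr
        return (world_pts - wire).ravel()

    # Identity transform start; wire initialised at the centroid of the
    # pixel positions pushed through the tracker poses alone.
    w0 = (np.einsum("nij,nj->ni", rot_tr, p_probe) + trans_tr).mean(axis=0)
    x0 = np.concatenate([np.zeros(6), w0])

    sol = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if sol.status <= 0:
        raise ConvergenceError(
            f"calibration solver did not converge (status {sol.status}, "
            f"{sol.nfev} function evaluations)"
        )

    t_rp, r_rp, wire = unpack(sol.x)
    res = residuals(sol.x).reshape(-1, 3)
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return CalibrationResult(
        probe_to_sensor=RigidTransform.from_rotation_translation(r_rp, t_rp),
        wire_point=wire.copy(),
        residual_rms=rms,
        n_observations=len(pix),
    )
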