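"""Parametric spine phantoms and simulated tracked-frame sweeps.

The phantom stands in for a scoliotic back scanned with a tracked linear
probe.  World axes: x lateral (right), y depth (into the body), z
longitudinal (caudal L5 at z = 0, cranial T1 at z = L).  The phantom is a
spinous-process ridge running along a parametric centerline: the lateral
deviation x_c(z) encodes the scoliotic curve, and the skin surface
y_skin(z) undulates to mimic the natural sagittal (kyphosis/lordosis)
profile.  The bony ridge sits a fixed distance below the skin, so a probe
swept in skin contact sees the bone at a constant image depth — the
geometric premise that makes nonplanar (probe-face-following) reslicing
outperform a fixed-depth planar slab.

Each simulated B-mode frame shows the classic sonographic signature of a
spinous process: a bright bone-surface arc with a dark acoustic shadow
beneath it (ultrasound does not penetrate bone), over a speckled
soft-tissue background.

The scoliosis severity readout is the spinous process angle (SPA): the
angle between tangents of the centerline at its most-tilted regions.  For
the built-in curve families it is available in closed form and stored as
``true_spa`` for end-to-end accuracy tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, List, Literal, Optional, Sequence

import numpy as np

from .geometry import FrameGeometry, Pose, RigidTransform, compose_chain, pose_to_matrix

__all__ = [
    "SpinePhantom",
    "ProbeTrajectory",
    "TrackedFrame",
    "PhantomConfigError",
    "TrajectoryExtentError",
    "make_spine_phantom",
    "ground_truth_spa",
    "make_sweep_trajectory",
    "simulate_scan",
]

CurveKind = Literal["straight", "c", "s", "piecewise"]


class PhantomConfigError(ValueError):
    """Invalid phantom geometry parameters."""


class TrajectoryExtentError(ValueError):
    """Probe trajectory leaves the phantom extent."""


@dataclass(frozen=True)
class TrackedFrame:
    """One B-mode image with its 6-DOF tracker pose."""

    image: np.ndarray  # (rows, cols) uint8; rows = depth, cols = lateral
    pose: Pose  # t_T_r sensor pose
    index: int


@dataclass(frozen=True)
class ProbeTrajectory:
    """An ordered sweep of sensor poses at fixed frame rate and speed."""

    poses: tuple[Pose, ...]
    frame_rate: float  # frames / s
    sweep_speed: float  # mm / s

    def __post_init__(self) -> None:
        tz = [p.tz for p in self.poses]
        if any(b < a for a, b in zip(tz, tz[1:])):
            raise ValueError("sweep must be monotonically non-decreasing in z")

    def __len__(self) -> int:
        return len(self.poses)


@dataclass(frozen=True)
class SpinePhantom:
    """Ground-truth spine geometry and acoustic appearance parameters.

    The centerline is x_c(z) for z in [0, length_mm]:

    * ``straight`` — x_c = 0 (SPA 0°).
    * ``c``        — half-sine bump A·sin(pi·z/L); single scoliotic curve,
      SPA = 2·atan(A·pi/L).
    * ``s``        — full sine A·sin(2·pi·z/L); double curve, each angle
      2·atan(2·A·pi/L).
    * ``piecewise``— two straight segments with slopes ``segment_slopes``
      meeting at mid-spine (C1-discontinuous; handy for exact-angle tests).
    """

    length_mm: float
    curve: CurveKind
    amplitude_mm: float
    vertebra_count: int
    process_radius_mm: float
    bone_depth_mm: float  # centre of the bony ridge below the skin surface
    skin_base_mm: float  # mean skin depth in world y
    skin_undulation_mm: float  # sagittal-curve amplitude (half range)
    skin_cycles: float
    background_intensity: float
    bone_surface_intensity: float
    shadow_attenuation: float  # fraction per mm below the bone surface
    speckle_sigma: float
    true_spa: float  # degrees, analytic
    segment_slopes: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise PhantomConfigError("length_mm must be positive")
        if self.process_radius_mm <= 0:
            raise PhantomConfigError("process_radius_mm must be positive")
        for name in ("background_intensity", "bone_surface_intensity"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise PhantomConfigError(f"{name} must be in [0, 255]")
        if self.shadow_attenuation < 0:
            raise PhantomConfigError("shadow_attenuation must be non-negative")

    # -- centerline geometry -----------------------------------------
    def lateral(self, z) -> np.ndarray:
        """Lateral deviation x_c(z) of the spinous ridge, mm."""
        z = np.asarray(z, dtype=float)
        L, A = self.length_mm, self.amplitude_mm
        if self.curve == "straight":
            return np.zeros_like(z)
        if self.curve == "c":
            return A * np.sin(np.pi * z / L)
        if self.curve == "s":
            return A * np.sin(2 * np.pi * z / L)
        # piecewise: two line segments meeting at L/2
        s1, s2 = self.segment_slopes
        mid = L / 2.0
        return np.where(z < mid, s1 * z, s1 * mid + s2 * (z - mid))

    def tangent_angle(self, z) -> np.ndarray:
        """Tangent angle of the centerline vs the scan axis, degrees."""
        z = np.asarray(z, dtype=float)
        L, A = self.length_mm, self.amplitude_mm
        if self.curve == "straight":
            slope = np.zeros_like(z)
        elif self.curve == "c":
            slope = A * np.pi / L * np.cos(np.pi * z / L)
        elif self.curve == "s":
            slope = 2 * A * np.pi / L * np.cos(2 * np.pi * z / L)
        else:
            s1, s2 = self.segment_slopes
            slope = np.where(z < L / 2.0, s1, s2)
        return np.degrees(np.arctan(slope))

    def skin_depth(self, z) -> np.ndarray:
        """World-y of the skin surface at longitudinal position z, mm."""
        z = np.asarray(z, dtype=float)
        return self.skin_base_mm + self.skin_undulation_mm * np.sin(
            2 * np.pi * self.skin_cycles * z / self.length_mm
        )

    def ridge_radius(self, z) -> np.ndarray:
        """Spinous-ridge radius, gently modulated per vertebra, mm."""
        z = np.asarray(z, dtype=float)
        mod = 0.85 + 0.15 * np.cos(2 * np.pi * self.vertebra_count * z / self.length_mm)
        return self.process_radius_mm * mod


def _analytic_spa(curve: CurveKind, length_mm: float, amplitude_mm: float,
                  segment_slopes: tuple[float, float]) -> float:
    if curve == "straight":
        return 0.0
    if curve == "c":
        return 2.0 * math.degrees(math.atan(amplitude_mm * math.pi / length_mm))
    if curve == "s":
        return 2.0 * math.degrees(math.atan(2.0 * amplitude_mm * math.pi / length_mm))
    s1, s2 = segment_slopes
    return abs(math.degrees(math.atan(s1)) - math.degrees(math.atan(s2)))


def _amplitude_for_spa(curve: CurveKind, length_mm: float, spa_deg: float) -> float:
    half = math.tan(math.radians(spa_deg / 2.0))
    if curve == "c":
        return half * length_mm / math.pi
    if curve == "s":
        return half * length_mm / (2.0 * math.pi)
    raise PhantomConfigError(f"target_spa is only supported for 'c'/'s' curves, not {curve!r}")


def make_spine_phantom(
    *,
    curve: CurveKind = "c",
    length_mm: float = 300.0,
    target_spa: Optional[float] = None,
    amplitude_mm: Optional[float] = None,
    segment_slopes: tuple[float, float] = (0.0, 0.0),
    vertebra_count: int = 17,
    process_radius_mm: float = 4.0,
    bone_depth_mm: float = 20.0,
    skin_base_mm: float = 0.0,
    skin_undulation_mm: float = 8.0,
    skin_cycles: float = 1.0,
    background_intensity: float = 120.0,
    bone_surface_intensity: float = 235.0,
    shadow_attenuation: float = 0.5,
    speckle_sigma: float = 10.0,
    seed: int = 0,
) -> SpinePhantom:
    """Construct a spine phantom; deterministic for a fixed seed.

    Either ``target_spa`` (degrees; the amplitude is solved in closed form)
    or ``amplitude_mm`` may be given for the ``c``/``s`` families.  Default
    geometry: 300 mm spine (L5→T1), bony ridge 20 mm below the skin so the
    default 5.6 mm coronal layer can bracket it, and an 8 mm sagittal skin
    undulation exceeding that layer thickness.
    """
    if curve in ("c", "s"):
        if target_spa is not None:
            amplitude_mm = _amplitude_for_spa(curve, length_mm, target_spa)
        elif amplitude_mm is None:
            amplitude_mm = _amplitude_for_spa(curve, length_mm, 20.0)
    else:
        amplitude_mm = 0.0 if amplitude_mm is None else amplitude_mm
    spa = _analytic_spa(curve, length_mm, amplitude_mm, segment_slopes)
    return SpinePhantom(
        length_mm=length_mm,
        curve=curve,
        amplitude_mm=float(amplitude_mm),
        vertebra_count=vertebra_count,
        process_radius_mm=process_radius_mm,
        bone_depth_mm=bone_depth_mm,
        skin_base_mm=skin_base_mm,
        skin_undulation_mm=skin_undulation_mm,
        skin_cycles=skin_cycles,
        background_intensity=background_intensity,
        bone_surface_intensity=bone_surface_intensity,
        shadow_attenuation=shadow_attenuation,
        speckle_sigma=speckle_sigma,
        true_spa=spa,
        segment_slopes=segment_slopes,
        seed=seed,
    )


def ground_truth_spa(phantom: SpinePhantom) -> float:
    """Analytic spinous process angle of the phantom, degrees."""
    return phantom.true_spa


def make_sweep_trajectory(
    phantom: SpinePhantom,
    geom: FrameGeometry,
    *,
    frame_rate: float = 25.0,
    sweep_speed: float = 10.0,
) -> ProbeTrajectory:
    """A slow upward sweep (default 25 frames/s at 10 mm/s, ~1 cm/s).

    The probe stays in skin contact (ty follows the skin profile, making
    the sweep surface nonplanar) and the operator keeps the spine centred
    laterally (tx follows the scoliotic centerline), as in a real scan.
    Frame count = floor(L / sweep_speed * frame_rate).
    """
    n = int(math.floor(phantom.length_mm / sweep_speed * frame_rate))
    dz = sweep_speed / frame_rate
    half_width = geom.width_mm / 2.0
    poses = []
    for i in range(n):
        z = i * dz
        poses.append(
            Pose(
                tx=float(phantom.lateral(z)) - half_width,
                ty=float(phantom.skin_depth(z)),
                tz=z,
                alpha=0.0,
                beta=0.0,
                gamma=0.0,
                timestamp=i / frame_rate,
            )
        )
    return ProbeTrajectory(poses=tuple(poses), frame_rate=frame_rate, sweep_speed=sweep_speed)


def _render_frame(
    phantom: SpinePhantom,
    probe_pose: Pose,
    geom: FrameGeometry,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rasterise one transverse B-mode frame at the probe pose.

    Bright bone-surface arc, exponential acoustic shadow beneath it,
    uniform soft-tissue background, additive Gaussian speckle.
    """
    z = probe_pose.tz
    cols = np.arange(geom.width) * geom.pixel_spacing_x + probe_pose.tx  # world x
    rows = np.arange(geom.height) * geom.pixel_spacing_y + probe_pose.ty  # world y
    img = np.full((geom.height, geom.width), phantom.background_intensity, dtype=float)

    if phantom.bone_surface_intensity > 0:
        xc = float(phantom.lateral(z))
        radius = float(phantom.ridge_radius(z))
        yc = float(phantom.skin_depth(z)) + phantom.bone_depth_mm
        dx = cols - xc
        inside = np.abs(dx) < radius
        if inside.any():
            # world-y of the bone surface per lateral position
            surf = yc - np.sqrt(np.maximum(radius**2 - dx[inside] ** 2, 0.0))
            below = rows[:, None] - surf[None, :]  # mm below the surface
            col_img = np.full((geom.height, inside.sum()), phantom.background_intensity)
            arc_half = 0.6  # mm, apparent thickness of the specular bone echo
            on_arc = np.abs(below) <= arc_half
            shadow = below > arc_half
            col_img[on_arc] = phantom.bone_surface_intensity
            col_img[shadow] = phantom.background_intensity * np.exp(
                -phantom.shadow_attenuation * below[shadow]
            )
            img[:, inside] = col_img

    if phantom.speckle_sigma > 0:
        img += rng.normal(0.0, phantom.speckle_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def simulate_scan(
    phantom: SpinePhantom,
    trajectory: ProbeTrajectory,
    geom: FrameGeometry,
    r_T_p: Optional[RigidTransform] = None,
    seed: int = 0,
) -> List[TrackedFrame]:
    """Simulate a tracked B-mode sweep over the phantom.

    ``trajectory`` poses describe the probe (image) frame; the recorded
    sensor poses are t_T_r = t_T_p · (r_T_p)⁻¹ so that composing the
    stream with the calibration transform downstream recovers the probe
    placement exactly.  Deterministic for a fixed seed.
    """
    if r_T_p is None:
        r_T_p = RigidTransform.identity()
    zs = np.array([p.tz for p in trajectory.poses])
    if zs.size and (zs.min() < -1e-9 or zs.max() > phantom.length_mm + 1e-9):
        raise TrajectoryExtentError(
            f"trajectory z range [{zs.min():.1f}, {zs.max():.1f}] mm exceeds "
            f"phantom extent [0, {phantom.length_mm}] mm"
        )
    rng = np.random.default_rng(seed)
    inv_rp = r_T_p.inverse()
    frames: List[TrackedFrame] = []
    for i, probe_pose in enumerate(trajectory.poses):
        img = _render_frame(phantom, probe_pose, geom, rng)
        t_T_p = pose_to_matrix(probe_pose)
        sensor_pose = (t_T_p @ inv_rp).to_pose()
        sensor_pose = Pose(
            sensor_pose.tx, sensor_pose.ty, sensor_pose.tz,
            sensor_pose.alpha, sensor_pose.beta, sensor_pose.gamma,
            timestamp=probe_pose.timestamp,
        )
        frames.append(TrackedFrame(image=img, pose=sensor_pose, index=i))
    return frames
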