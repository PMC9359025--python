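"""Shared fixtures: small-scale phantoms, simulated sweeps and calibration data.

Unit tests run on reduced frames (120 x 160) and short phantoms so the
default suite stays fast; full-scale 480 x 640 runs live in the
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import sonospine as ss
from sonospine.geometry import Pose, pixel_to_probe, pose_to_matrix


@pytest.fixture(scope="session")
def small_geom() -> ss.FrameGeometry:
    """Reduced 120x160 frames at 0.3 mm pixels (48 x 36 mm field)."""
    return ss.FrameGeometry(0.3, 0.3, width=160, height=120)


@pytest.fixture(scope="session")
def full_geom() -> ss.FrameGeometry:
    """The system's native 480-row x 640-column frames at 0.1 mm pixels."""
    return ss.FrameGeometry(0.1, 0.1)


def render_phantom_image(phantom, geom, *, depth=18.0, mode="nonplanar",
                         spacing_y=0.5, seed=0, sweep_speed=10.0, frame_rate=25.0,
                         offset=10.0):
    """Simulate a sweep and produce the final coronal image + session."""
    traj = ss.make_sweep_trajectory(phantom, geom, frame_rate=frame_rate,
                                    sweep_speed=sweep_speed)
    frames = ss.simulate_scan(phantom, traj, geom, seed=seed)
    sr = ss.compute_scan_range(traj.poses[0], traj.poses[-1], offset, geom)
    sess = ss.IncrementalSession(sr, ss.LayerSpec(depth=depth, mode=mode), geom,
                                 spacing_y=spacing_y)
    sess.process_batch(frames)
    return sess.finalize(force=True), sess


@pytest.fixture(scope="session")
def small_sweep(small_geom):
    """A short (120 mm) 20-degree sweep at reduced scale: (phantom, frames, range)."""
    phantom = ss.make_spine_phantom(target_spa=20.0, length_mm=120.0,
                                    skin_undulation_mm=4.0, seed=11)
    traj = ss.make_sweep_trajectory(phantom, small_geom, sweep_speed=20.0)
    frames = ss.simulate_scan(phantom, traj, small_geom, seed=11)
    scan_range = ss.compute_scan_range(traj.poses[0], traj.poses[-1], 8.0, small_geom)
    return phantom, frames, scan_range


def simulate_crosswire_observations(true_rp, wire, geom, n, rng, *,
                                    pos_noise=0.0, ang_noise=0.0):
    """Forward-simulate cross-wire calibration observations.

    For each observation a random orientation and wire pixel are drawn and
    the sensor translation is solved so the transformed pixel lands exactly
    on the wire point; optional Gaussian pose noise is then added.
    """
    pixels, poses = [], []
    for _ in range(n):
        ang = rng.uniform(-40, 40, 3)
        u = rng.uniform(0.1 * geom.width, 0.9 * geom.width)
        v = rng.uniform(0.1 * geom.height, 0.9 * geom.height)
        p_probe = pixel_to_probe(u, v, geom)
        rot = pose_to_matrix(Pose(0, 0, 0, *ang)).rotation
        t = wire - rot @ true_rp.apply(p_probe)
        if pos_noise or ang_noise:
            t = t + rng.normal(0.0, pos_noise, 3)
            ang = ang + rng.normal(0.0, ang_noise, 3)
        pixels.append((u, v))
        poses.append(Pose(*t, *ang))
    return np.array(pixels), poses
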