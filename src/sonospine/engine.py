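"""The real-time imaging loop: scan range, incremental C_new updates, storage.

The session mirrors the clinical workflow: record the lower (caudal to
L5) and upper (cranial to T1) boundary poses, expand their probe
footprints by an operator offset into a cubic scan range, then stream
frames.  Each incoming batch touches only a small part of the coronal
image — the bounding bin box of its in-layer pixels, padded by one bin so
border hole filling sees its neighbours.  Only that region (``C_new``) is
re-averaged and hole-filled; the contrast stretch is recomputed over the
whole image, as displayed.  When a frame pose crosses the upper boundary
the sweep is finished and the final image (global hole fill + contrast)
is written as an 8-bit bitmap.

Because bin accumulators are order-invariant sums of 8-bit intensities,
the final accumulators after any batching equal those of a single-shot
render bit for bit, and re-running hole fill globally at finalisation
makes the final image identical to the batch oracle.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry import FrameGeometry, Pose, RigidTransform, compose_chain, pose_to_matrix
from .phantom import TrackedFrame
from .rendering import (
    CoronalGrid,
    LayerSpec,
    contrast_adjust,
    hole_fill,
    select_layer_pixels,
)

__all__ = [
    "ScanRange",
    "UpdateRegion",
    "BatchLogEntry",
    "SessionFinishedError",
    "BoundaryError",
    "compute_scan_range",
    "IncrementalSession",
]

SCAN_AXIS = 2  # world z


class BoundaryError(ValueError):
    """Scan boundaries inverted (upper not above lower on the scan axis)."""


class SessionFinishedError(RuntimeError):
    """A batch arrived after the upper boundary was reached."""


@dataclass(frozen=True)
class ScanRange:
    """Cubic scanning range derived from the two boundary poses.

    ``lower_bound``/``upper_bound`` are the probe-origin scan-axis (z)
    coordinates of the boundary poses; ``cube`` is the axis-aligned box
    containing both probe footprints expanded by ``offset`` on every face,
    shape (3, 2) as [[xmin, xmax], [ymin, ymax], [zmin, zmax]] in mm.
    """

    lower_bound: float
    upper_bound: float
    offset: float
    cube: np.ndarray

    def __post_init__(self) -> None:
        if self.lower_bound >= self.upper_bound:
            raise BoundaryError("lower boundary must be below the upper boundary")


@dataclass(frozen=True)
class UpdateRegion:
    """Inclusive bin-index bounds (row0, row1, col0, col1) of C_new."""

    row0: int
    row1: int
    col0: int
    col1: int

    def as_tuple(self) -> Tuple[int, int, int, int]:
        return (self.row0, self.row1, self.col0, self.col1)


@dataclass
class BatchLogEntry:
    batch: int
    frames: int
    cnew: Optional[Tuple[int, int, int, int]]
    millis: float


def _footprint_corners(pose: Pose, geom: FrameGeometry,
                       c_T_t: RigidTransform, r_T_p: RigidTransform) -> np.ndarray:
    """World corners of the probe image rectangle at a sensor pose, (4, 3)."""
    c_T_p = compose_chain(c_T_t, pose_to_matrix(pose), r_T_p)
    w, d = geom.width_mm, geom.depth_mm
    corners = np.array(
        [[0.0, 0.0, 0.0], [w, 0.0, 0.0], [0.0, d, 0.0], [w, d, 0.0]]
    )
    return c_T_p.apply(corners)


def compute_scan_range(
    lower_pose: Pose,
    upper_pose: Pose,
    offset: float,
    geom: FrameGeometry,
    c_T_t: Optional[RigidTransform] = None,
    r_T_p: Optional[RigidTransform] = None,
) -> ScanRange:
    """Cubic scan range from the two recorded boundary poses.

    The cube is the bounding box of the two probe footprints expanded by
    ``offset`` on every face.  The upper pose must lie strictly above the
    lower pose on the scan axis.
    """
    c_T_t = c_T_t or RigidTransform.identity()
    r_T_p = r_T_p or RigidTransform.identity()
    lo_z = compose_chain(c_T_t, pose_to_matrix(lower_pose), r_T_p).translation[SCAN_AXIS]
    up_z = compose_chain(c_T_t, pose_to_matrix(upper_pose), r_T_p).translation[SCAN_AXIS]
    if up_z <= lo_z:
        raise BoundaryError(
            f"upper boundary (z={up_z:.2f}) must be above lower boundary (z={lo_z:.2f})"
        )
    pts = np.vstack(
        [
            _footprint_corners(lower_pose, geom, c_T_t, r_T_p),
            _footprint_corners(upper_pose, geom, c_T_t, r_T_p),
        ]
    )
    cube = np.stack([pts.min(axis=0) - offset, pts.max(axis=0) + offset], axis=1)
    return ScanRange(lower_bound=float(lo_z), upper_bound=float(up_z),
                     offset=float(offset), cube=cube)


class IncrementalSession:
    """Streaming coronal render with C_new-restricted updates.

    Parameters
    ----------
    scan_range : ScanRange
        Sizes the coronal grid (lateral x cube and longitudinal z cube).
    layer : LayerSpec
        Coronal band to reslice (planar or nonplanar).
    geom : FrameGeometry
        Pixel spacings of the incoming frames.
    r_T_p, c_T_t : RigidTransform, optional
        Calibration and user reconstruction-frame transforms (identity
        by default); each frame's chain c_T_p = c_T_t · t_T_r · r_T_p.
    spacing_y : float
        Longitudinal bin spacing, mm (operator choice, default 0.5).
    spacing_x : float, optional
        Lateral bin spacing, mm; defaults to the frame's lateral pixel
        spacing (set by the transducer).
    """

    def __init__(
        self,
        scan_range: ScanRange,
        layer: LayerSpec,
        geom: FrameGeometry,
        r_T_p: Optional[RigidTransform] = None,
        c_T_t: Optional[RigidTransform] = None,
        spacing_y: float = 0.5,
        spacing_x: Optional[float] = None,
        hole_fill_connectivity: int = 8,
        contrast_percentiles: Tuple[float, float] = (1.0, 99.0),
    ):
        self.range = scan_range
        self.layer = layer
        self.geom = geom
        self.r_T_p = r_T_p or RigidTransform.identity()
        self.c_T_t = c_T_t or RigidTransform.identity()
        self.connectivity = hole_fill_connectivity
        self.percentiles = contrast_percentiles
        sx = spacing_x if spacing_x is not None else geom.pixel_spacing_x
        self.grid = CoronalGrid.from_extent(
            x_range=tuple(scan_range.cube[0]),
            z_range=tuple(scan_range.cube[2]),
            spacing_x=sx,
            spacing_y=spacing_y,
        )
        self.frames_processed = 0
        self.batches_processed = 0
        self.finished = False
        self.log: List[BatchLogEntry] = []
        # running display values incl. region-restricted hole fill
        self._display_values = self.grid.values()
        self.display: Optional[np.ndarray] = None  # last 8-bit frame shown
        self._out_of_order_warned = False
        self._last_z = -np.inf

    # -- the per-batch update ----------------------------------------
    def process_batch(
        self, batch: Sequence[TrackedFrame]
    ) -> Tuple[Optional[UpdateRegion], Optional[np.ndarray]]:
        """Deposit one batch of frames and update only its C_new region.

        Returns the padded update region and the 8-bit display crop of it
        (both None when the batch contributed no in-layer pixel).  The
        contrast stretch is recomputed over the whole image.
        """
        if self.finished:
            raise SessionFinishedError("the sweep already reached the upper boundary")
        if len(batch) == 0:
            raise ValueError("batch must contain at least one frame")
        t0 = time.perf_counter()
        bbox = None
        for frame in batch:
            z = pose_to_matrix(frame.pose).translation[SCAN_AXIS]
            if z < self._last_z - 1e-9 and not self._out_of_order_warned:
                import warnings

                warnings.warn(
                    "frame poses are not in ascending scan order; accumulators "
                    "are order-invariant but an upward sweep was expected",
                    stacklevel=2,
                )
                self._out_of_order_warned = True
            self._last_z = max(self._last_z, z)
            c_T_p = compose_chain(self.c_T_t, pose_to_matrix(frame.pose), self.r_T_p)
            pts, vals = select_layer_pixels(frame, self.geom, self.layer, c_T_p)
            info = self.grid.deposit(pts, vals)
            if info.touched_bbox is not None:
                bbox = _merge_bbox(bbox, info.touched_bbox)
            self.frames_processed += 1
        self.batches_processed += 1

        region = None
        crop = None
        if bbox is not None:
            nr, nc = self.grid.shape
            region = UpdateRegion(
                max(bbox[0] - 1, 0),
                min(bbox[1] + 1, nr - 1),
                max(bbox[2] - 1, 0),
                min(bbox[3] + 1, nc - 1),
            )
            r0, r1, c0, c1 = region.as_tuple()
            # re-average + hole-fill C_new only, then global contrast
            filled_region = hole_fill(
                self.grid, connectivity=self.connectivity, region=region.as_tuple()
            )
            self._display_values[r0 : r1 + 1, c0 : c1 + 1] = filled_region[
                r0 : r1 + 1, c0 : c1 + 1
            ]
            self.display = contrast_adjust(self._display_values, *self.percentiles)
            crop = self.display[r0 : r1 + 1, c0 : c1 + 1].copy()
        millis = (time.perf_counter() - t0) * 1000.0
        self.log.append(BatchLogEntry(self.batches_processed, len(batch),
                                      region.as_tuple() if region else None, millis))
        return region, crop

    def check_stop(self, frame: TrackedFrame) -> bool:
        """True (and mark the session finished) once the frame pose reaches
        the upper boundary on the scan axis (boundary inclusive)."""
        z = compose_chain(
            self.c_T_t, pose_to_matrix(frame.pose), self.r_T_p
        ).translation[SCAN_AXIS]
        if z >= self.range.upper_bound:
            self.finished = True
            return True
        return False

    def run_stream(
        self, frames: Sequence[TrackedFrame], batch_size: int = 1
    ) -> "IncrementalSession":
        """Replay a stream in batches until exhausted or the stop pose is hit."""
        batch: List[TrackedFrame] = []
        stopped = False
        for frame in frames:
            if self.check_stop(frame):
                stopped = True
                break
            batch.append(frame)
            if len(batch) >= batch_size:
                self.process_batch(batch)
                batch = []
        if batch:
            # flush the tail even if the sweep ended mid-batch
            self.finished = False
            self.process_batch(batch)
        self.finished = stopped
        return self

    # -- finalisation -------------------------------------------------
    def final_image(self) -> np.ndarray:
        """Whole-grid hole fill + contrast stretch as the stored 8-bit image."""
        filled = hole_fill(self.grid, connectivity=self.connectivity)
        return contrast_adjust(filled, *self.percentiles)

    def finalize(self, path=None, force: bool = False) -> np.ndarray:
        """Produce (and optionally save as BMP) the final coronal image.

        Requires a finished sweep unless ``force``.  Logs a timing summary.
        """
        if not self.finished and not force:
            raise SessionFinishedError(
                "session not finished; pass force=True to finalise anyway"
            )
        img = self.final_image()
        if path is not None:
            from .streamio import write_bitmap

            write_bitmap(img, path)
        return img

    # -- reporting ----------------------------------------------------
    def timing_summary(self) -> dict:
        total_ms = sum(e.millis for e in self.log)
        return {
            "frames": self.frames_processed,
            "batches": self.batches_processed,
            "seconds": total_ms / 1000.0,
            "frames_per_second": (
                self.frames_processed / (total_ms / 1000.0) if total_ms > 0 else float("nan")
            ),
        }


def _merge_bbox(a, b):
    if a is None:
        return b
    return (min(a[0], b[0]), max(a[1], b[1]), min(a[2], b[2]), max(a[3], b[3]))
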