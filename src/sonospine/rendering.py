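"""Narrow-band coronal rendering: layer selection, bin filling, hole filling.

The coronal spine image is formed directly from the raw tracked frames,
skipping 3D voxel reconstruction.  Per frame, only the pixels inside a
thin layer (default thickness 5.6 mm) are kept:

* ``nonplanar`` mode measures the layer depth from the probe face along
  the image depth axis, so the band follows the skin (the developable
  surface swept by the probe face) and tracks curved anatomy;
* ``planar`` mode keeps pixels whose world depth coordinate falls in a
  fixed slab, the conventional planar reslice.

Selected pixels are deposited into a regular coronal grid by pixel-
nearest-neighbour (PNN-style) bin filling — each bin shows the mean of
all pixels that landed in it — and remaining empty bins are filled from
their immediate nonempty neighbours.  Contrast is adjusted over the whole
image with a percentile linear stretch.

Bins are half-open: a coordinate exactly on an upper bin boundary belongs
to the next bin.  Hole filling is single-pass, reads only the original
emptiness flags (no cascading) and never touches the accumulators; it
produces a display copy only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Tuple

import numpy as np
from scipy.ndimage import convolve

from .geometry import FrameGeometry, RigidTransform, pixel_to_probe
from .phantom import TrackedFrame

__all__ = [
    "LayerSpec",
    "CoronalGrid",
    "UpdateInfo",
    "EmptyGridError",
    "select_layer_pixels",
    "bin_fill",
    "hole_fill",
    "contrast_adjust",
]

LayerMode = Literal["planar", "nonplanar"]

# default layer thickness, mm
DEFAULT_THICKNESS = 5.6


class EmptyGridError(ValueError):
    """Operation requires at least one nonempty bin."""


@dataclass(frozen=True)
class LayerSpec:
    """Coronal band: depth to the layer top and band thickness, mm.

    In nonplanar mode the depth is measured from the probe face along the
    image depth axis of every frame; in planar mode it is a world-frame
    depth (y) slab.
    """

    depth: float
    thickness: float = DEFAULT_THICKNESS
    mode: LayerMode = "nonplanar"

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("layer thickness must be positive")
        if self.depth < 0:
            raise ValueError("layer depth must be non-negative")
        if self.mode not in ("planar", "nonplanar"):
            raise ValueError(f"unknown layer mode {self.mode!r}")


@dataclass
class UpdateInfo:
    """Bookkeeping from one bin-fill call."""

    touched_bbox: Optional[Tuple[int, int, int, int]]  # (row0, row1, col0, col1) inclusive
    n_deposited: int
    n_dropped: int
    dropped_intensity_sum: float


class CoronalGrid:
    """Regular coronal pixel lattice with running sum/count accumulators.

    Rows index the longitudinal (z) axis with spacing ``spacing_y``
    (operator-chosen, default 0.5 mm); columns index the lateral (x) axis
    with spacing ``spacing_x`` (typically the transducer pixel spacing).
    ``origin`` is the world (x, z) of the lower corner of bin (0, 0).
    A bin's display value is sum/count; bins with count 0 are empty.
    """

    def __init__(
        self,
        n_rows: int,
        n_cols: int,
        spacing_x: float,
        spacing_y: float,
        origin: Tuple[float, float] = (0.0, 0.0),
    ):
        if n_rows <= 0 or n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if spacing_x <= 0 or spacing_y <= 0:
            raise ValueError("grid spacings must be positive")
        self.sums = np.zeros((n_rows, n_cols), dtype=np.float64)
        self.counts = np.zeros((n_rows, n_cols), dtype=np.int64)
        self.spacing_x = float(spacing_x)
        self.spacing_y = float(spacing_y)
        self.origin = (float(origin[0]), float(origin[1]))
        self.n_dropped = 0
        self.dropped_intensity_sum = 0.0

    @classmethod
    def from_extent(
        cls,
        x_range: Tuple[float, float],
        z_range: Tuple[float, float],
        spacing_x: float,
        spacing_y: float,
    ) -> "CoronalGrid":
        """Grid covering the given world x (lateral) and z (longitudinal) ranges."""
        nx = max(1, int(np.ceil((x_range[1] - x_range[0]) / spacing_x)))
        nz = max(1, int(np.ceil((z_range[1] - z_range[0]) / spacing_y)))
        return cls(nz, nx, spacing_x, spacing_y, origin=(x_range[0], z_range[0]))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.sums.shape

    def bin_indices(self, points: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """(row, col) bin of each world point (n, 3); half-open bins."""
        x = points[:, 0]
        z = points[:, 2]
        cols = np.floor((x - self.origin[0]) / self.spacing_x).astype(np.int64)
        rows = np.floor((z - self.origin[1]) / self.spacing_y).astype(np.int64)
        return rows, cols

    def values(self) -> np.ndarray:
        """Display values: sum/count where filled, NaN where empty."""
        with np.errstate(invalid="ignore", divide="ignore"):
            v = self.sums / self.counts
        v[self.counts == 0] = np.nan
        return v

    def filled_mask(self) -> np.ndarray:
        return self.counts > 0

    def deposit(self, points: np.ndarray, intensities: np.ndarray) -> UpdateInfo:
        """Accumulate (world point, intensity) samples into bins.

        Points outside the grid extent are dropped and logged.  Returns the
        inclusive bounding box of touched bins (None if nothing landed).
        """
        points = np.asarray(points, dtype=float)
        intensities = np.asarray(intensities, dtype=float)
        if points.size == 0:
            return UpdateInfo(None, 0, 0, 0.0)
        if not np.all(np.isfinite(points)):
            raise ValueError("points must be finite")
        rows, cols = self.bin_indices(points)
        nr, nc = self.shape
        ok = (rows >= 0) & (rows < nr) & (cols >= 0) & (cols < nc)
        n_drop = int((~ok).sum())
        drop_sum = float(intensities[~ok].sum()) if n_drop else 0.0
        self.n_dropped += n_drop
        self.dropped_intensity_sum += drop_sum
        rows, cols, vals = rows[ok], cols[ok], intensities[ok]
        if rows.size == 0:
            return UpdateInfo(None, 0, n_drop, drop_sum)
        np.add.at(self.sums, (rows, cols), vals)
        np.add.at(self.counts, (rows, cols), 1)
        bbox = (int(rows.min()), int(rows.max()), int(cols.min()), int(cols.max()))
        return UpdateInfo(bbox, int(rows.size), n_drop, drop_sum)


def select_layer_pixels(
    frame: TrackedFrame,
    geom: FrameGeometry,
    layer: LayerSpec,
    c_T_p: RigidTransform,
) -> Tuple[np.ndarray, np.ndarray]:
    """Pixels of a frame inside the coronal layer, as world points.

    Returns ``(points, intensities)`` with points (n, 3) in mm.  Nonplanar
    mode keeps the rows whose image depth v*spacing_y lies in
    [depth, depth + thickness); planar mode keeps pixels whose world depth
    (y) lies in that slab.  An empty selection is not an error.
    """
    img = frame.image
    h, w = img.shape
    lo, hi = layer.depth, layer.depth + layer.thickness

    if layer.mode == "nonplanar":
        v_depth = np.arange(h) * geom.pixel_spacing_y
        rows = np.nonzero((v_depth >= lo) & (v_depth < hi))[0]
        if rows.size == 0:
            return np.empty((0, 3)), np.empty((0,))
        uu, vv = np.meshgrid(np.arange(w), rows)
        pts = c_T_p.apply(pixel_to_probe(uu.ravel(), vv.ravel(), geom))
        return pts, img[rows, :].ravel().astype(np.float64)

    # planar: transform every pixel, keep those inside the world-depth slab
    uu, vv = np.meshgrid(np.arange(w), np.arange(h))
    pts = c_T_p.apply(pixel_to_probe(uu.ravel(), vv.ravel(), geom))
    sel = (pts[:, 1] >= lo) & (pts[:, 1] < hi)
    return pts[sel], img.ravel()[sel].astype(np.float64)


def bin_fill(grid: CoronalGrid, points: np.ndarray, intensities: np.ndarray) -> CoronalGrid:
    """PNN-style bin filling: deposit samples, each bin averaging its hits."""
    grid.deposit(points, intensities)
    return grid


def _neighbor_kernel(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        k = np.ones((3, 3))
        k[1, 1] = 0.0
    elif connectivity == 4:
        k = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    else:
        raise ValueError("connectivity must be 4 or 8")
    return k


def hole_fill(
    grid: CoronalGrid,
    connectivity: int = 8,
    region: Optional[Tuple[int, int, int, int]] = None,
) -> np.ndarray:
    """Fill empty bins from the mean of their immediate nonempty neighbours.

    Single pass over original emptiness flags: a bin filled in this pass
    never feeds another, so the result is order-independent.  Bins whose
    whole neighbourhood is empty stay NaN.  Accumulators are untouched —
    the return value is a display copy.

    ``region`` (row0, row1, col0, col1, inclusive) restricts which empty
    bins are filled; neighbour values may still be read from outside it.
    """
    if not grid.filled_mask().any():
        raise EmptyGridError("cannot hole-fill a fully empty grid")
    values = grid.values()
    filled = grid.filled_mask()
    k = _neighbor_kernel(connectivity)
    out = values.copy()
    if region is not None:
        # work on the region plus a 1-bin halo so neighbours outside it count
        nr, nc = filled.shape
        r0, r1, c0, c1 = region
        R0, R1 = max(r0 - 1, 0), min(r1 + 1, nr - 1)
        C0, C1 = max(c0 - 1, 0), min(c1 + 1, nc - 1)
        sub_vals = values[R0 : R1 + 1, C0 : C1 + 1]
        sub_fill = filled[R0 : R1 + 1, C0 : C1 + 1]
        nsum = convolve(np.where(sub_fill, sub_vals, 0.0), k, mode="constant", cval=0.0)
        ncnt = convolve(sub_fill.astype(np.float64), k, mode="constant", cval=0.0)
        fillable = (~sub_fill) & (ncnt > 0)
        mask = np.zeros_like(fillable)
        mask[r0 - R0 : r1 - R0 + 1, c0 - C0 : c1 - C0 + 1] = True
        fillable &= mask
        sub_out = out[R0 : R1 + 1, C0 : C1 + 1]
        sub_out[fillable] = nsum[fillable] / ncnt[fillable]
        return out
    vals0 = np.where(filled, values, 0.0)
    nsum = convolve(vals0, k, mode="constant", cval=0.0)
    ncnt = convolve(filled.astype(np.float64), k, mode="constant", cval=0.0)
    fillable = (~filled) & (ncnt > 0)
    out[fillable] = nsum[fillable] / ncnt[fillable]
    return out


def contrast_adjust(
    image: np.ndarray,
    p_low: float = 1.0,
    p_high: float = 99.0,
) -> np.ndarray:
    """Whole-image percentile linear stretch to 8 bit.

    Nonempty (non-NaN) pixels are rescaled so that the [p_low, p_high]
    percentile range maps to [0, 255] (clipping outside); empty pixels
    render as 0.  A constant image maps to mid-grey 128.
    """
    img = np.asarray(image, dtype=float)
    valid = np.isfinite(img)
    if not valid.any():
        raise EmptyGridError("contrast adjustment needs at least one nonempty pixel")
    vals = img[valid]
    lo, hi = np.percentile(vals, [p_low, p_high])
    out = np.zeros(img.shape, dtype=np.uint8)
    if hi <= lo:
        out[valid] = 128
        return out
    scaled = (img[valid] - lo) / (hi - lo) * 255.0
    out[valid] = np.clip(np.rint(scaled), 0, 255).astype(np.uint8)
    return out
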