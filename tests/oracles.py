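"""Independent brute-force oracles used by the test suite.

Each function re-derives an expected result by the most direct possible
route (per-pixel loops, explicit group-by, sorted-percentile formula) so
the vectorised implementations are checked against genuinely independent
code paths.
"""

from __future__ import annotations

import numpy as np

from sonospine.geometry import FrameGeometry, RigidTransform, pixel_to_probe
from sonospine.rendering import CoronalGrid, LayerSpec


def select_layer_pixels_bruteforce(image, geom: FrameGeometry, layer: LayerSpec,
                                   c_T_p: RigidTransform):
    """Per-pixel loop over the whole frame testing the band condition."""
    pts, vals = [], []
    lo, hi = layer.depth, layer.depth + layer.thickness
    h, w = image.shape
    for v in range(h):
        for u in range(w):
            p = c_T_p.apply(pixel_to_probe(u, v, geom))
            if layer.mode == "nonplanar":
                keep = lo <= v * geom.pixel_spacing_y < hi
            else:
                keep = lo <= p[1] < hi
            if keep:
                pts.append(p)
                vals.append(float(image[v, u]))
    if not pts:
        return np.empty((0, 3)), np.empty((0,))
    return np.array(pts), np.array(vals)


def bin_means_bruteforce(grid: CoronalGrid, points, intensities):
    """Explicit group-by-bin averaging over a point cloud."""
    sums = {}
    counts = {}
    dropped = 0.0
    n_drop = 0
    nr, nc = grid.shape
    for p, val in zip(points, intensities):
        col = int(np.floor((p[0] - grid.origin[0]) / grid.spacing_x))
        row = int(np.floor((p[2] - grid.origin[1]) / grid.spacing_y))
        if 0 <= row < nr and 0 <= col < nc:
            sums[(row, col)] = sums.get((row, col), 0.0) + val
            counts[(row, col)] = counts.get((row, col), 0) + 1
        else:
            dropped += val
            n_drop += 1
    means = {k: sums[k] / counts[k] for k in sums}
    return means, counts, n_drop, dropped


def hole_fill_bruteforce(values, filled, connectivity=8):
    """Pixel-by-pixel single-pass neighbourhood mean on original emptiness."""
    nr, nc = values.shape
    out = values.copy()
    if connectivity == 8:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if (dr, dc) != (0, 0)]
    else:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    for r in range(nr):
        for c in range(nc):
            if filled[r, c]:
                continue
            neigh = []
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc and filled[rr, cc]:
                    neigh.append(values[rr, cc])
            out[r, c] = float(np.mean(neigh)) if neigh else np.nan
    return out


def percentile_sorted(values, q):
    """Percentile by explicit sort + linear interpolation (q in [0, 100])."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 1:
        return float(v[0])
    pos = q / 100.0 * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)


def contrast_stretch_bruteforce(image, p_low=1.0, p_high=99.0):
    """Per-pixel percentile stretch; empty (NaN) pixels -> 0."""
    img = np.asarray(image, dtype=float)
    valid = np.isfinite(img)
    vals = img[valid]
    lo = percentile_sorted(vals, p_low)
    hi = percentile_sorted(vals, p_high)
    out = np.zeros(img.shape, dtype=np.uint8)
    it = np.nditer(img, flags=["multi_index"])
    for x in it:
        idx = it.multi_index
        if not np.isfinite(x):
            continue
        if hi <= lo:
            out[idx] = 128
        else:
            s = (float(x) - lo) / (hi - lo) * 255.0
            out[idx] = np.uint8(min(255.0, max(0.0, np.rint(s))))
    return out
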