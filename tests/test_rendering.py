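"""Rendering primitives vs brute-force oracles: layer selection, bin and
hole filling, contrast stretch."""

import numpy as np
import pytest

import sonospine as ss
from sonospine.geometry import FrameGeometry, Pose, RigidTransform, pose_to_matrix
from sonospine.phantom import TrackedFrame
from sonospine.rendering import (
    CoronalGrid,
    EmptyGridError,
    LayerSpec,
    contrast_adjust,
    hole_fill,
    select_layer_pixels,
)

from oracles import (
    bin_means_bruteforce,
    contrast_stretch_bruteforce,
    hole_fill_bruteforce,
    select_layer_pixels_bruteforce,
)


def tiny_frame(rng, h=24, w=32) -> TrackedFrame:
    img = rng.integers(0, 256, size=(h, w), dtype=np.uint8)
    pose = Pose(*rng.uniform(-20, 20, 3), *rng.uniform(-30, 30, 3))
    return TrackedFrame(image=img, pose=pose, index=0)


class TestSelectLayerPixels:
    def test_nonplanar_band_is_row_arithmetic(self):
        """Depth 20 mm, thickness 5.6 mm at 0.1 mm/px selects rows 200..255."""
        geom = FrameGeometry(0.1, 0.1)
        img = np.arange(480 * 640, dtype=np.uint32).reshape(480, 640) % 256
        frame = TrackedFrame(image=img.astype(np.uint8), pose=Pose(0, 0, 0, 0, 0, 0),
                             index=0)
        layer = LayerSpec(depth=20.0, thickness=5.6, mode="nonplanar")
        pts, vals = select_layer_pixels(frame, geom, layer, RigidTransform.identity())
        v_rows = np.unique(np.round(pts[:, 1] / 0.1).astype(int))
        assert v_rows.min() == 200 and v_rows.max() == 255
        assert len(vals) == 56 * 640

    def test_planar_parallel_frame_outside_slab_is_empty(self):
        """A frame rotated 90 deg about x lies parallel to the slab; placed
        outside it, nothing is selected."""
        geom = FrameGeometry(0.3, 0.3, width=32, height=24)
        img = np.full((24, 32), 100, dtype=np.uint8)
        frame = TrackedFrame(image=img, pose=Pose(0, 0, 0, 0, 0, 90), index=0)
        layer = LayerSpec(depth=30.0, thickness=5.0, mode="planar")
        pts, vals = select_layer_pixels(
            frame, geom, layer, pose_to_matrix(frame.pose)
        )
        assert len(vals) == 0

    @pytest.mark.parametrize("mode", ["planar", "nonplanar"])
    def test_matches_per_pixel_oracle(self, mode):
        geom = FrameGeometry(0.4, 0.4, width=32, height=24)
        rng = np.random.default_rng(20)
        for _ in range(10):
            frame = tiny_frame(rng)
            c_T_p = pose_to_matrix(frame.pose)
            layer = LayerSpec(depth=float(rng.uniform(0, 8)),
                              thickness=float(rng.uniform(1, 6)), mode=mode)
            pts, vals = select_layer_pixels(frame, geom, layer, c_T_p)
            opts, ovals = select_layer_pixels_bruteforce(frame.image, geom, layer, c_T_p)
            assert pts.shape == opts.shape
            if len(vals):
                order = np.lexsort(pts.T)
                oorder = np.lexsort(opts.T)
                assert np.allclose(pts[order], opts[oorder], atol=1e-9)
                assert np.allclose(vals[order], ovals[oorder])


class TestBinFill:
    def test_two_pixels_average_in_one_bin(self):
        grid = CoronalGrid(4, 4, 1.0, 1.0)
        pts = np.array([[0.5, 0.0, 0.5], [0.7, 0.0, 0.3]])
        grid.deposit(pts, np.array([80.0, 120.0]))
        assert grid.values()[0, 0] == pytest.approx(100.0)
        assert grid.counts[0, 0] == 2

    def test_uniform_intensity_fills_touched_bins_uniformly(self):
        grid = CoronalGrid(6, 6, 1.0, 1.0)
        rng = np.random.default_rng(21)
        pts = np.column_stack(
            [rng.uniform(0, 6, 200), np.zeros(200), rng.uniform(0, 6, 200)]
        )
        grid.deposit(pts, np.full(200, 55.0))
        v = grid.values()
        assert np.allclose(v[np.isfinite(v)], 55.0)

    def test_matches_group_by_oracle_and_conserves_intensity(self):
        rng = np.random.default_rng(22)
        for _ in range(10):
            grid = CoronalGrid(8, 10, 0.7, 1.3, origin=(-2.0, -3.0))
            n = int(rng.integers(10, 300))
            pts = np.column_stack(
                [rng.uniform(-5, 7, n), rng.uniform(-1, 1, n), rng.uniform(-5, 12, n)]
            )
            vals = rng.uniform(0, 255, n)
            grid.deposit(pts, vals)
            means, counts, n_drop, drop_sum = bin_means_bruteforce(grid, pts, vals)
            v = grid.values()
            for (r, c), m in means.items():
                assert v[r, c] == pytest.approx(m, abs=1e-9)
            assert grid.counts.sum() == sum(counts.values())
            assert grid.n_dropped == n_drop
            # conservation: binned sum + dropped sum = total input intensity
            assert grid.sums.sum() + grid.dropped_intensity_sum == pytest.approx(
                vals.sum(), rel=1e-12
            )

    def test_order_invariance(self):
        rng = np.random.default_rng(23)
        pts = np.column_stack(
            [rng.uniform(0, 5, 150), np.zeros(150), rng.uniform(0, 5, 150)]
        )
        vals = rng.integers(0, 256, 150).astype(float)
        g1 = CoronalGrid(5, 5, 1.0, 1.0)
        g1.deposit(pts, vals)
        perm = rng.permutation(150)
        g2 = CoronalGrid(5, 5, 1.0, 1.0)
        g2.deposit(pts[perm], vals[perm])
        assert np.array_equal(g1.counts, g2.counts)
        assert np.allclose(g1.sums, g2.sums, atol=1e-9)

    def test_upper_boundary_goes_to_higher_bin(self):
        grid = CoronalGrid(4, 4, 1.0, 1.0)
        grid.deposit(np.array([[1.0, 0.0, 2.0]]), np.array([10.0]))
        assert grid.counts[2, 1] == 1


def sparse_grid(rng, nr=12, nc=15, fill=0.4) -> CoronalGrid:
    grid = CoronalGrid(nr, nc, 1.0, 1.0)
    mask = rng.random((nr, nc)) < fill
    counts = rng.integers(1, 4, (nr, nc))
    grid.counts[mask] = counts[mask]
    grid.sums[mask] = rng.uniform(0, 255, (nr, nc))[mask] * grid.counts[mask]
    return grid


class TestHoleFill:
    def test_neighbour_mean_example(self):
        grid = CoronalGrid(3, 3, 1.0, 1.0)
        for (r, c), v in {(0, 1): 10.0, (1, 0): 20.0, (1, 2): 30.0, (2, 1): 40.0}.items():
            grid.sums[r, c] = v
            grid.counts[r, c] = 1
        out = hole_fill(grid)
        assert out[1, 1] == pytest.approx(25.0)

    def test_dense_grid_unchanged(self):
        rng = np.random.default_rng(24)
        grid = sparse_grid(rng, fill=1.01)
        assert np.allclose(hole_fill(grid), grid.values())

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_bruteforce_oracle(self, connectivity):
        rng = np.random.default_rng(25)
        for _ in range(10):
            grid = sparse_grid(rng)
            out = hole_fill(grid, connectivity=connectivity)
            oracle = hole_fill_bruteforce(grid.values(), grid.filled_mask(),
                                          connectivity)
            assert np.allclose(out, oracle, atol=1e-9, equal_nan=True)

    def test_single_pass_no_cascade(self):
        """A bin filled in this pass never feeds another empty bin."""
        grid = CoronalGrid(1, 4, 1.0, 1.0)
        grid.sums[0, 0] = 50.0
        grid.counts[0, 0] = 1
        out = hole_fill(grid)
        assert out[0, 1] == pytest.approx(50.0)
        assert np.isnan(out[0, 2]) and np.isnan(out[0, 3])

    def test_accumulators_untouched(self):
        rng = np.random.default_rng(26)
        grid = sparse_grid(rng)
        sums, counts = grid.sums.copy(), grid.counts.copy()
        hole_fill(grid)
        assert np.array_equal(grid.sums, sums)
        assert np.array_equal(grid.counts, counts)

    def test_empty_grid_rejected(self):
        with pytest.raises(EmptyGridError):
            hole_fill(CoronalGrid(3, 3, 1.0, 1.0))


class TestContrastAdjust:
    def test_full_range_image_nearly_unchanged(self):
        img = np.linspace(0, 255, 1000).reshape(10, 100)
        out = contrast_adjust(img, p_low=0.0, p_high=100.0)
        assert np.abs(out.astype(float) - img).max() <= 0.5

    def test_constant_image_maps_to_mid_grey(self):
        img = np.full((5, 5), 42.0)
        assert np.all(contrast_adjust(img) == 128)

    def test_empty_pixels_render_black(self):
        img = np.full((4, 4), np.nan)
        img[0, 0], img[3, 3] = 10.0, 200.0
        out = contrast_adjust(img)
        assert out[1, 1] == 0

    def test_matches_percentile_stretch_oracle(self):
        rng = np.random.default_rng(27)
        for _ in range(10):
            img = rng.uniform(0, 255, (15, 20))
            img[rng.random((15, 20)) < 0.3] = np.nan
            assert np.array_equal(contrast_adjust(img), contrast_stretch_bruteforce(img))

    def test_fully_empty_rejected(self):
        with pytest.raises(EmptyGridError):
            contrast_adjust(np.full((3, 3), np.nan))
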