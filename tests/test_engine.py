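"""Incremental engine: scan range, C_new updates, batch/stream equivalence."""

import numpy as np
import pytest

import sonospine as ss
from sonospine.engine import (
    BoundaryError,
    IncrementalSession,
    SessionFinishedError,
    compute_scan_range,
)
from sonospine.geometry import Pose, RigidTransform, compose_chain, pose_to_matrix
from sonospine.phantom import TrackedFrame
from sonospine.rendering import EmptyGridError, LayerSpec


def make_session(scan_range, geom, depth=18.0, mode="nonplanar", spacing_y=0.5):
    return IncrementalSession(scan_range, LayerSpec(depth=depth, mode=mode), geom,
                              spacing_y=spacing_y)


class TestComputeScanRange:
    def test_scan_axis_extent_arithmetic(self, full_geom):
        sr = compute_scan_range(Pose(0, 0, 0, 0, 0, 0), Pose(0, 0, 400, 0, 0, 0),
                                10.0, full_geom)
        assert sr.cube[2, 0] == pytest.approx(-10.0)
        assert sr.cube[2, 1] == pytest.approx(410.0)
        assert sr.lower_bound == 0.0 and sr.upper_bound == 400.0

    def test_zero_offset_is_exact_bounding_box(self, full_geom):
        sr = compute_scan_range(Pose(0, 0, 0, 0, 0, 0), Pose(0, 0, 100, 0, 0, 0),
                                0.0, full_geom)
        assert sr.cube[0, 0] == pytest.approx(0.0)
        assert sr.cube[0, 1] == pytest.approx(full_geom.width_mm)
        assert sr.cube[1, 1] == pytest.approx(full_geom.depth_mm)

    def test_matches_corner_set_oracle(self, full_geom):
        """Cube equals brute-force min/max over the 2 x 4 transformed image
        corners, expanded by the offset."""
        rng = np.random.default_rng(30)
        for _ in range(10):
            lo = Pose(*rng.uniform(-50, 50, 2), 0.0, *rng.uniform(-20, 20, 3))
            up = Pose(*rng.uniform(-50, 50, 2), float(rng.uniform(50, 300)),
                      *rng.uniform(-20, 20, 3))
            off = float(rng.uniform(0, 15))
            try:
                sr = compute_scan_range(lo, up, off, full_geom)
            except BoundaryError:
                continue
            corners = []
            for pose in (lo, up):
                t = pose_to_matrix(pose)
                w, d = full_geom.width_mm, full_geom.depth_mm
                for c in ([0, 0, 0], [w, 0, 0], [0, d, 0], [w, d, 0]):
                    corners.append(t.apply(np.array(c, dtype=float)))
            corners = np.array(corners)
            assert np.allclose(sr.cube[:, 0], corners.min(axis=0) - off, atol=1e-9)
            assert np.allclose(sr.cube[:, 1], corners.max(axis=0) + off, atol=1e-9)

    def test_inverted_boundaries_rejected(self, full_geom):
        with pytest.raises(BoundaryError):
            compute_scan_range(Pose(0, 0, 100, 0, 0, 0), Pose(0, 0, 0, 0, 0, 0),
                               5.0, full_geom)


class TestProcessBatch:
    def test_out_of_layer_batch_leaves_grid_unchanged(self, small_sweep, small_geom):
        """A planar slab far below every frame selects nothing: empty C_new."""
        _, frames, sr = small_sweep
        sess = make_session(sr, small_geom, depth=200.0, mode="planar")
        region, crop = sess.process_batch(frames[:3])
        assert region is None and crop is None
        assert sess.grid.counts.sum() == 0
        assert sess.frames_processed == 3

    def test_stream_vs_single_batch_bit_identical(self, small_sweep, small_geom):
        """The module's core property: any batching yields the same final
        accumulators and final image as a single-shot render."""
        _, frames, sr = small_sweep
        one = make_session(sr, small_geom)
        one.process_batch(frames)
        rng = np.random.default_rng(31)
        stream = make_session(sr, small_geom)
        i = 0
        while i < len(frames):
            n = int(rng.integers(1, 12))
            stream.process_batch(frames[i : i + n])
            i += n
        assert np.array_equal(one.grid.sums, stream.grid.sums)
        assert np.array_equal(one.grid.counts, stream.grid.counts)
        assert np.array_equal(one.finalize(force=True), stream.finalize(force=True))

    def test_filled_region_grows_monotonically(self, small_sweep, small_geom):
        _, frames, sr = small_sweep
        sess = make_session(sr, small_geom)
        prev = np.zeros(sess.grid.shape, dtype=bool)
        for i in range(0, len(frames), 20):
            sess.process_batch(frames[i : i + 20])
            now = sess.grid.filled_mask()
            assert np.all(now[prev])  # earlier filled region is a subset
            prev = now

    def test_locality_outside_cnew(self, small_sweep, small_geom):
        """Bins outside every returned C_new keep their initial counts."""
        _, frames, sr = small_sweep
        sess = make_session(sr, small_geom)
        touched = np.zeros(sess.grid.shape, dtype=bool)
        for i in range(0, 60, 10):
            region, _ = sess.process_batch(frames[i : i + 10])
            if region:
                touched[region.row0 : region.row1 + 1,
                        region.col0 : region.col1 + 1] = True
        assert np.all(sess.grid.counts[~touched] == 0)

    def test_batch_after_finish_rejected(self, small_sweep, small_geom):
        _, frames, sr = small_sweep
        sess = make_session(sr, small_geom)
        sess.finished = True
        with pytest.raises(SessionFinishedError):
            sess.process_batch(frames[:1])

    def test_update_region_within_grid(self, small_sweep, small_geom):
        _, frames, sr = small_sweep
        sess = make_session(sr, small_geom)
        region, crop = sess.process_batch(frames[:5])
        nr, nc = sess.grid.shape
        assert 0 <= region.row0 <= region.row1 < nr
        assert 0 <= region.col0 <= region.col1 < nc
        assert crop.shape == (region.row1 - region.row0 + 1,
                              region.col1 - region.col0 + 1)


class TestStopAndFinalize:
    def test_stop_is_boundary_inclusive(self, small_geom):
        sr = compute_scan_range(Pose(0, 0, 0, 0, 0, 0), Pose(0, 0, 100, 0, 0, 0),
                                5.0, small_geom)
        sess = make_session(sr, small_geom)
        img = np.zeros((small_geom.height, small_geom.width), dtype=np.uint8)
        below = TrackedFrame(img, Pose(0, 0, 99.9, 0, 0, 0), 0)
        at = TrackedFrame(img, Pose(0, 0, 100.0, 0, 0, 0), 1)
        assert not sess.check_stop(below)
        assert not sess.finished
        assert sess.check_stop(at)
        assert sess.finished

    def test_stop_index_matches_linear_scan_oracle(self, small_sweep, small_geom):
        phantom, frames, _ = small_sweep
        bound = frames[len(frames) // 2].pose.tz
        sr = compute_scan_range(frames[0].pose,
                                Pose(0, 0, bound, 0, 0, 0), 5.0, small_geom)
        sess = make_session(sr, small_geom)
        stop_idx = next(i for i, f in enumerate(frames) if sess.check_stop(f))
        oracle = min(i for i, f in enumerate(frames) if f.pose.tz >= bound)
        assert stop_idx == oracle

    def test_run_stream_counts_frames_and_stops(self, small_sweep, small_geom):
        phantom, frames, sr = small_sweep
        sess = make_session(sr, small_geom)
        sess.run_stream(frames, batch_size=16)
        # the final frame hits the upper boundary pose, so it is excluded
        assert sess.frames_processed == len(frames) - 1
        assert sess.finished

    def test_empty_session_finalize_raises(self, small_geom):
        sr = compute_scan_range(Pose(0, 0, 0, 0, 0, 0), Pose(0, 0, 50, 0, 0, 0),
                                5.0, small_geom)
        sess = make_session(sr, small_geom)
        with pytest.raises(EmptyGridError):
            sess.finalize(force=True)

    def test_finalized_file_round_trips(self, small_sweep, small_geom, tmp_path):
        _, frames, sr = small_sweep
        sess = make_session(sr, small_geom)
        sess.process_batch(frames)
        out = tmp_path / "final.bmp"
        img = sess.finalize(out, force=True)
        from sonospine.streamio import read_image

        assert np.array_equal(read_image(out), img)

    def test_unfinished_finalize_requires_force(self, small_sweep, small_geom):
        _, frames, sr = small_sweep
        sess = make_session(sr, small_geom)
        sess.process_batch(frames[:10])
        with pytest.raises(SessionFinishedError):
            sess.finalize()
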