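"""Track metrics, coverage filtering, rose histograms, drift, invasion."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from durokit import migration as M
from durokit.exceptions import DurokitError


def make_track(points, tid="t", dt=60.0):
    pts = np.asarray(points, dtype=float)
    return M.Track(tid, np.arange(len(pts)) * dt, pts[:, 0], pts[:, 1])


class TestTrackMetrics:
    def test_straight_monotone_path_is_maximally_direct(self):
        m = M.track_metrics(make_track([(0, 0), (1, 0), (2, 0), (5, 0)]))
        assert m.directionality == 1.0
        assert m.fmi_parallel == 1.0
        assert m.end_angle == 0.0

    def test_right_angle_path_hand_computed(self):
        m = M.track_metrics(make_track([(0, 0), (3, 0), (3, 4)]))
        assert m.path_length == pytest.approx(7.0)
        assert m.net_displacement == pytest.approx(5.0)
        assert m.directionality == pytest.approx(5 / 7)
        assert m.fmi_parallel == pytest.approx(3 / 7)
        assert m.fmi_perpendicular == pytest.approx(4 / 7)

    def test_closed_loop_zero_direction(self):
        m = M.track_metrics(make_track([(0, 0), (5, 5), (0, 0)]))
        assert m.directionality == 0.0 and m.fmi_parallel == 0.0

    def test_mean_speed_uses_timestamps(self):
        tr = M.Track("s", [0.0, 30.0, 90.0], [0.0, 1.0, 3.0], [0.0, 0.0, 0.0])
        assert M.track_metrics(tr).mean_speed == pytest.approx(3.0 / 1.5)

    def test_zero_elapsed_time_impossible(self):
        with pytest.raises(ValueError):
            M.Track("z", [0.0, 0.0], [0.0, 1.0], [0.0, 0.0])

    @given(st.lists(st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
                    min_size=2, max_size=12))
    def test_bounds_and_pythagorean_decomposition(self, pts):
        m = M.track_metrics(make_track(pts))
        assert 0.0 <= m.directionality <= 1.0 + 1e-12
        assert abs(m.fmi_parallel) <= m.directionality + 1e-12
        assert (m.fmi_parallel**2 + m.fmi_perpendicular**2
                <= m.directionality**2 + 1e-9)

    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=2, max_size=8),
           st.floats(0, 2 * np.pi))
    def test_rotation_invariance(self, pts, angle):
        c, s = np.cos(angle), np.sin(angle)
        rot = [(c * x - s * y, s * x + c * y) for x, y in pts]
        m0 = M.track_metrics(make_track(pts), gradient_axis=(1.0, 0.0))
        m1 = M.track_metrics(make_track(rot), gradient_axis=(c, s))
        for attr in ("path_length", "net_displacement", "directionality",
                     "fmi_parallel", "fmi_perpendicular"):
            assert getattr(m0, attr) == pytest.approx(getattr(m1, attr), abs=1e-9)


class TestFilterTracks:
    def test_strictly_more_than_ten_percent(self):
        # 120-frame recording at 60 s: 13-frame span kept, 12-frame dropped
        duration = 120 * 60.0
        keep = make_track([(i, 0) for i in range(14)], "keep")  # span 13 frames
        drop = make_track([(i, 0) for i in range(13)], "drop")  # span exactly 10%
        out = M.filter_tracks([keep, drop], duration)
        assert [t.track_id for t in out] == ["keep"]

    def test_zero_coverage_keeps_all(self):
        tracks = [make_track([(0, 0), (1, 1)])]
        assert M.filter_tracks(tracks, 1e6, min_coverage=0.0) == tracks

    def test_empty_input(self):
        assert M.filter_tracks([], 100.0) == []


class TestRoseHistogram:
    def test_forward_tracks_fill_forward_bin(self):
        tracks = [make_track([(0, 0), (10, 0)], f"t{i}") for i in range(3)]
        rose = M.rose_histogram(tracks)
        hit = np.nonzero(rose.counts)[0]
        assert len(hit) == 1 and rose.counts[hit[0]] == 3
        assert rose.bin_edges[hit[0]] < 0.0 <= rose.bin_edges[hit[0] + 1]

    def test_mirrored_tracks_symmetric(self):
        base = [[(0, 0), (3, 1)], [(0, 0), (2, 5)], [(0, 0), (-1, 2)]]
        tracks = [make_track(p, f"a{i}") for i, p in enumerate(base)]
        tracks += [make_track([(x, -y) for x, y in p], f"b{i}")
                   for i, p in enumerate(base)]
        rose = M.rose_histogram(tracks)
        assert np.array_equal(rose.counts, rose.counts[::-1])

    def test_unbiased_angles_nearly_uniform(self, rng):
        ang = rng.uniform(-np.pi, np.pi, 1000)
        tracks = [make_track([(0, 0), (np.cos(a), np.sin(a))], f"u{i}")
                  for i, a in enumerate(ang)]
        rose = M.rose_histogram(tracks)
        assert rose.counts.sum() == 1000
        assert M.resultant_length(rose) < 0.1

    def test_zero_net_tracks_counted_excluded(self):
        tracks = [make_track([(0, 0), (1, 1), (0, 0)]),
                  make_track([(0, 0), (1, 0)], "m")]
        rose = M.rose_histogram(tracks)
        assert rose.n_excluded == 1 and rose.counts.sum() == 1


class TestDriftCorrect:
    def _mirrored_pair(self, steps, dt=60.0):
        """Two tracks with opposite motion: ensemble median step is zero."""
        pts = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
        a = M.Track("a", np.arange(len(pts)) * dt, pts[:, 0], pts[:, 1])
        b = M.Track("b", np.arange(len(pts)) * dt, -pts[:, 0], -pts[:, 1])
        return [a, b]

    def test_constant_shift_removed_exactly(self, rng):
        true = self._mirrored_pair(rng.normal(0, 1, (10, 2)))
        drift = np.arange(11)[:, None] * np.array([1.0, -2.0])
        shifted = [M.Track(t.track_id, t.t, t.x + drift[:, 0], t.y + drift[:, 1])
                   for t in true]
        out = M.drift_correct(shifted)
        for got, want in zip(out, true):
            np.testing.assert_allclose(got.x, want.x, atol=1e-9)
            np.testing.assert_allclose(got.y, want.y, atol=1e-9)

    def test_no_drift_unchanged(self, rng):
        tracks = self._mirrored_pair(rng.normal(0, 1, (6, 2)))
        out = M.drift_correct(tracks)
        for got, want in zip(out, tracks):
            np.testing.assert_allclose(got.x, want.x, atol=1e-12)

    def test_random_walk_drift_removed_on_ensemble(self, rng):
        n, T = 20, 30
        walks = rng.normal(0, 0.2, (n, T, 2)).cumsum(axis=1)
        walks -= np.median(walks, axis=0, keepdims=True)  # zero-median motion
        drift = rng.normal(0, 2.0, (T, 2)).cumsum(axis=0)
        tracks = [M.Track(f"w{i}", np.arange(T) * 60.0,
                          walks[i, :, 0] + drift[:, 0],
                          walks[i, :, 1] + drift[:, 1]) for i in range(n)]
        out = M.drift_correct(tracks)
        steps = np.array([[np.diff(t.x), np.diff(t.y)] for t in out])
        assert np.abs(np.median(steps, axis=0)).max() < 1e-9

    def test_single_track_warns(self):
        tr = make_track([(0, 0), (1, 1)])
        with pytest.warns(UserWarning):
            out = M.drift_correct([tr])
        assert out == [tr]


class TestInvasion:
    BOUNDARY = [(-10.0, 50.0), (110.0, 50.0)]  # horizontal; "left" = above

    def _track(self, y0, y1, i):
        x = 5.0 + 10.0 * (i % 10)  # spread across the field of view
        return make_track([(x, y0), (x, y1)], f"c{i}")

    def test_confined_tracks_zero(self):
        tracks = [self._track(10, 30, i) for i in range(5)]
        assert M.invasion_index(tracks, self.BOUNDARY, "left") == 0.0

    def test_all_crossing_one(self):
        tracks = [self._track(10, 90, i) for i in range(5)]
        assert M.invasion_index(tracks, self.BOUNDARY, "left") == 1.0

    def test_partial_crossing_fraction(self):
        tracks = [self._track(10, 90, i) for i in range(3)]
        tracks += [self._track(10, 20, 10 + i) for i in range(7)]
        assert M.invasion_index(tracks, self.BOUNDARY, "left") == pytest.approx(0.3)

    def test_non_partitioning_boundary_rejected(self):
        tracks = [self._track(10, 90, i) for i in range(3)]
        with pytest.raises(DurokitError, match="partition"):
            M.invasion_index(tracks, [(40.0, 50.0), (60.0, 50.0)], "left")
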