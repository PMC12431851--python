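"""Generators: determinism, ground-truth recovery, structural nulls."""

import numpy as np
import pandas as pd
import pytest

from durokit import afm, gradients as G, migration as M, simulate as sim, \
    substrates as S, tumor as T


class TestDeterminism:
    def test_force_curves_byte_identical(self):
        a, _ = sim.gen_force_curves(9, 4e3, n_curves=3)
        b, _ = sim.gen_force_curves(9, 4e3, n_curves=3)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.force, cb.force)

    def test_field_byte_identical(self):
        a, fa = sim.gen_stiffness_field(9, "fibrotic")
        b, fb = sim.gen_stiffness_field(9, "fibrotic")
        np.testing.assert_array_equal(a.grid, b.grid)
        assert fa == fb

    def test_tracks_byte_identical(self, shallow):
        cfg = sim.SimulationConfig(seed=9, n=5, duration=3600.0)
        a, _ = sim.gen_tracks(shallow, cfg)
        b, _ = sim.gen_tracks(shallow, cfg)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.x, tb.x)
            np.testing.assert_array_equal(ta.y, tb.y)

    def test_flux_and_fibers_reproducible(self):
        ta, _ = sim.gen_flux_table(9)
        tb, _ = sim.gen_flux_table(9)
        pd.testing.assert_frame_equal(ta, tb)
        fa, _ = sim.gen_fibers(9, n=5)
        fb, _ = sim.gen_fibers(9, n=5)
        for a, b in zip(fa, fb):
            np.testing.assert_array_equal(a.points, b.points)

    def test_streams_independent_across_generators(self):
        # drawing curves must not shift the track stream for the same root seed
        cfg = sim.SimulationConfig(seed=5, n=3, duration=1800.0)
        a, _ = sim.gen_tracks(S.uniform_pattern(), cfg)
        sim.gen_force_curves(5, 4e3)
        b, _ = sim.gen_tracks(S.uniform_pattern(), cfg)
        np.testing.assert_array_equal(a[0].x, b[0].x)


class TestForceCurveTruth:
    def test_noiseless_fit_recovers_exactly(self):
        curves, truth = sim.gen_force_curves(1, 7.5e3, noise_frac=0)
        fit = afm.fit_hertz(curves[0])
        assert fit.modulus == pytest.approx(truth["E_true_Pa"], rel=1e-6)

    def test_curves_reach_the_force_cap(self):
        curves, _ = sim.gen_force_curves(1, 4e3, noise_frac=0)
        assert curves[0].force[-1] == pytest.approx(16e-9, rel=1e-6)


class TestStiffnessFieldTruth:
    def test_zero_amplitude_healthy_is_uniform(self):
        m, foci = sim.gen_stiffness_field(3, "healthy", healthy_amplitude=0.0)
        assert foci == []
        assert np.ptp(m.grid) == 0.0
        assert G.average_slope(m, seed=1).average_slope == 0.0

    def test_healthy_slopes_are_shallow(self):
        m, _ = sim.gen_stiffness_field(3, "healthy")
        assert G.average_slope(m, 50, seed=1).average_slope < 100.0

    def test_fibrotic_foci_recovered(self):
        m, foci = sim.gen_stiffness_field(3, "fibrotic")
        det = G.detect_peaks_valleys(m, min_prominence=2e3)
        for f in foci:
            assert any(d[2] == f["kind"]
                       and abs(d[0][0] - f["x_um"]) <= m.pitch
                       and abs(d[0][1] - f["y_um"]) <= m.pitch for d in det)


class TestTracks:
    def test_unbiased_walkers_have_no_net_direction(self, shallow):
        cfg = sim.SimulationConfig(seed=2, n=300, bias_strength=0.0,
                                   duration=6 * 3600.0)
        tracks, _ = sim.gen_tracks(shallow, cfg)
        fmi = [M.track_metrics(t).fmi_parallel for t in tracks]
        se = np.std(fmi) / np.sqrt(len(fmi))
        assert abs(np.mean(fmi)) < 3 * se

    def test_biased_walkers_climb_the_gradient(self, shallow):
        cfg = sim.SimulationConfig(seed=2, n=300, bias_strength=0.1)
        tracks, _ = sim.gen_tracks(shallow, cfg)
        fmi = [M.track_metrics(t).fmi_parallel for t in tracks]
        assert np.mean(fmi) > 0.3
        rose = M.rose_histogram(tracks)
        centers = 0.5 * (rose.bin_edges[:-1] + rose.bin_edges[1:])
        assert abs(centers[int(np.argmax(rose.counts))]) <= 20.0

    def test_uniform_pattern_neutralizes_any_bias(self):
        pat = S.uniform_pattern()
        cfg0 = sim.SimulationConfig(seed=4, n=20, bias_strength=0.0,
                                    duration=3600.0)
        cfg1 = sim.SimulationConfig(seed=4, n=20, bias_strength=5.0,
                                    duration=3600.0)
        a, _ = sim.gen_tracks(pat, cfg0)
        b, _ = sim.gen_tracks(pat, cfg1)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.x, tb.x)

    def test_walkers_stay_inside_extent(self, step):
        cfg = sim.SimulationConfig(seed=6, n=50, bias_strength=0.5,
                                   duration=6 * 3600.0)
        tracks, _ = sim.gen_tracks(step, cfg)
        w, h = step.extent
        for t in tracks:
            assert t.x.min() >= 0 and t.x.max() <= w
            assert t.y.min() >= 0 and t.y.max() <= h


class TestFluxAndFibers:
    def test_indices_recovered_exactly(self):
        table, truth = sim.gen_flux_table(8, n_animals=6)
        out = T.metastatic_index(table).set_index("animal_id")
        for animal, want in truth.items():
            assert out.loc[animal, "metastatic_index"] == pytest.approx(
                want, rel=1e-12)

    def test_zero_metastatic_fraction(self):
        table, truth = sim.gen_flux_table(8, metastatic_fraction_mean=0.0)
        out = T.metastatic_index(table)
        assert (out["metastatic_index"] == 0).all()
        assert all(v == 0.0 for v in truth.values())

    def test_fiber_cohorts_separate(self):
        straight, _ = sim.gen_fibers(3, "straight_aligned", n=100)
        curly, _ = sim.gen_fibers(3, "curly", n=100)
        rs = np.median([T.curvature_ratio(f) for f in straight])
        rc = np.median([T.curvature_ratio(f) for f in curly])
        assert rs > 0.95
        assert rc < rs
        assert T.fiber_population_summary(straight)["alignment_score"] > 0.8

    def test_zero_wiggle_fiber_perfectly_straight(self):
        fibers, _ = sim.gen_fibers(1, "straight_aligned", n=1, wiggle_um=0.0)
        assert T.curvature_ratio(fibers[0]) == pytest.approx(1.0)
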