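"""Substrate pattern geometry: moduli, gradients, regions, rasterization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from durokit import substrates as S
from durokit.exceptions import OutOfExtentError, UnsupportedKindError

# unit cell of the default step pattern: soft [0,200), ramp [200,240),
# stiff [240,340), ramp down [340,380)
STIFF_CENTER = (290.0, 50.0)
SOFT_CENTER = (100.0, 50.0)
MID_RAMP = (220.0, 50.0)


class TestStiffnessAt:
    @pytest.mark.parametrize("point,expected", [
        (STIFF_CENTER, 40e3),          # plateau of a stiff stripe
        (SOFT_CENTER, 4e3),            # plateau of a soft stripe
        (MID_RAMP, 22e3),              # midpoint of the linear transition
        ((290.0 + 380.0, 50.0), 40e3),  # one period over
    ])
    def test_step_pattern_values(self, step, point, expected):
        assert S.stiffness_at(step, point) == pytest.approx(expected)

    def test_linear_gradient_interpolates(self, shallow):
        # 4 kPa + 36 Pa/µm * 250 µm = 13 kPa a quarter of the way up
        assert S.stiffness_at(shallow, (250.0, 100.0)) == pytest.approx(13e3)

    def test_out_of_extent_names_coordinate(self, step):
        with pytest.raises(OutOfExtentError, match=r"-5"):
            S.stiffness_at(step, (-5.0, 10.0))

    def test_island_center_is_soft(self):
        pat = S.island_pattern(extent=(600.0, 600.0), island_radius=100.0)
        assert S.stiffness_at(pat, (300.0, 300.0)) == pytest.approx(1e3)

    @given(st.floats(0.0, 1000.0), st.floats(0.0, 1000.0))
    def test_bounded_between_end_moduli(self, x, y):
        pat = S.step_pattern()
        e = S.stiffness_at(pat, (x, y))
        assert pat.E_soft <= e <= pat.E_stiff

    @given(st.floats(0.0, 600.0), st.floats(0.0, 600.0))
    def test_island_bounded(self, x, y):
        pat = S.island_pattern(extent=(600.0, 600.0), island_radius=100.0)
        assert pat.E_soft <= S.stiffness_at(pat, (x, y)) <= pat.E_stiff

    @given(st.floats(0.0, 240.0), st.floats(0.0, 100.0))
    def test_periodicity(self, x, y):
        pat = S.step_pattern(extent=(1000.0, 100.0))
        e0 = S.stiffness_at(pat, (x, y))
        e1 = S.stiffness_at(pat, (x + pat.period, y))
        assert e1 == pytest.approx(e0, rel=1e-9, abs=1e-6)


class TestGradients:
    @pytest.mark.parametrize("kwargs,expected", [
        (dict(E_soft=4e3, E_stiff=40e3, transition_width=40.0), 900.0),
        (dict(E_soft=4e3, E_stiff=40e3, transition_width=1000.0), 36.0),
        (dict(E_soft=10e3, E_stiff=10e3, transition_width=40.0), 0.0),
    ])
    def test_nominal_gradient(self, kwargs, expected):
        pat = S.SubstratePattern("step_stripes", **kwargs)
        assert S.nominal_gradient(pat) == pytest.approx(expected)

    def test_nominal_gradient_rejects_uniform(self):
        with pytest.raises(UnsupportedKindError):
            S.nominal_gradient(S.uniform_pattern())

    def test_local_gradient_uniform_is_zero(self):
        g = S.local_gradient(S.uniform_pattern(), (500.0, 500.0))
        assert np.allclose(g, 0.0)

    def test_local_gradient_mid_ramp(self, step):
        g = S.local_gradient(step, MID_RAMP)
        assert np.allclose(g, (900.0, 0.0))

    def test_local_gradient_linear(self, shallow):
        g = S.local_gradient(shallow, (500.0, 100.0))
        assert np.allclose(g, (36.0, 0.0))

    def test_finite_difference_matches_nominal_in_ramp(self, step):
        # |FD gradient| at mid-transition agrees with the design gradient
        h = 0.1
        e1 = S.stiffness_at(step, (MID_RAMP[0] + h / 2, MID_RAMP[1]))
        e0 = S.stiffness_at(step, (MID_RAMP[0] - h / 2, MID_RAMP[1]))
        assert (e1 - e0) / h == pytest.approx(S.nominal_gradient(step), rel=0.01)


class TestRegions:
    def test_plateau_labels(self, step):
        assert S.region_of(step, STIFF_CENTER) == S.STIFF
        assert S.region_of(step, SOFT_CENTER) == S.SOFT

    def test_transition_excluded_by_default(self, step):
        assert S.region_of(step, MID_RAMP) == S.TRANSITION

    def test_midpoint_rule_splits_ramp(self, step):
        assert S.region_of(step, (221.0, 50.0), rule="midpoint") == S.STIFF
        assert S.region_of(step, (219.0, 50.0), rule="midpoint") == S.SOFT

    def test_area_fractions_analytic(self, step):
        fr = S.region_area_fractions(step)
        assert fr[S.SOFT] == pytest.approx(200 / 380)
        assert fr[S.STIFF] == pytest.approx(100 / 380)
        assert fr[S.TRANSITION] == pytest.approx(80 / 380)


class TestConstructionAndRaster:
    @pytest.mark.parametrize("kwargs", [
        dict(E_soft=-1.0, E_stiff=40e3),
        dict(E_soft=40e3, E_stiff=4e3),
        dict(E_soft=4e3, E_stiff=40e3, transition_width=0.0),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            S.SubstratePattern("step_stripes", **kwargs)

    def test_rasterize_samples_pixel_centers(self, shallow):
        m = S.rasterize(shallow, 10.0)
        assert m.shape == (50, 100)
        # first pixel centre at x = 5 µm: 4 kPa + 36 * 5
        assert m.grid[0, 0] == pytest.approx(4e3 + 36.0 * 5.0)

    def test_dict_roundtrip(self, step):
        assert S.SubstratePattern.from_dict(step.to_dict()).to_dict() == step.to_dict()
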