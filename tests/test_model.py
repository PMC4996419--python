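"""Unit and property tests for the deterministic model core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossfeed.errors import InvalidParameterError, NoThresholdError
from crossfeed.model import (
    ModelParams,
    PopulationState,
    map_concentration_to_a,
    monoculture_equilibrium,
    monoculture_viability_threshold,
    rhs,
    rhs_xy,
    saturation_factor,
)


class TestSaturationFactor:
    @pytest.mark.parametrize(
        "s, kappa, expected",
        [
            (0.0, 0.12, 0.0),  # zero nutrient gives zero growth
            (0.12, 0.12, 0.5),  # half-saturation at s = kappa by definition
            (0.48, 0.12, 0.8),  # 0.48 / 0.60
        ],
    )
    def test_reference_values(self, s, kappa, expected):
        assert saturation_factor(s, kappa) == pytest.approx(expected, abs=1e-12)

    def test_rejects_invalid(self):
        with pytest.raises(InvalidParameterError):
            saturation_factor(-0.1, 0.12)
        with pytest.raises(InvalidParameterError):
            saturation_factor(0.1, 0.0)

    @given(st.floats(min_value=0.0, max_value=1e3),
           st.floats(min_value=1e-6, max_value=10.0))
    @settings(max_examples=200, deadline=None)
    def test_bounded_in_unit_interval(self, s, kappa):
        g = saturation_factor(s, kappa)
        assert 0.0 <= g < 1.0

    @given(st.floats(min_value=1e-9, max_value=100.0),
           st.floats(min_value=1e-9, max_value=100.0))
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing(self, s, ds):
        assert saturation_factor(s + ds, 0.12) > saturation_factor(s, 0.12)


class TestRhs:
    def test_origin_is_fixed_point(self, default_params):
        for a in (0.0, 0.1, 5.0):
            assert rhs(PopulationState(0, 0), default_params.replace(a=a)) == (0, 0)

    def test_hand_evaluated_interior_derivatives(self, default_params):
        # independent hand evaluation at X = Y = 1/4, a = 0.09:
        # g_x = 0.34/0.46, g_y = 0.59/0.71, logistic factor 1/2
        p = default_params.replace(a=0.09)
        dX, dY = rhs(PopulationState(0.25, 0.25), p)
        exp_dx = 1.0 * 0.25 * (0.34 / 0.46) * 0.5 - 0.5 * 0.25
        exp_dy = 0.925 * 0.25 * (0.59 / 0.71) * 0.5 - 0.5 * 0.25
        assert dX == pytest.approx(exp_dx, abs=1e-15)
        assert dY == pytest.approx(exp_dy, abs=1e-15)
        assert dX == pytest.approx(-0.0326, abs=1e-4)
        assert dY == pytest.approx(-0.0289, abs=1e-4)

    def test_lone_strain_without_nutrient_decays(self, default_params):
        p = default_params.replace(a=0.0)
        dX, dY = rhs(PopulationState(0.3, 0.0), p)
        assert dX == pytest.approx(-p.delta * 0.3)
        assert dY == 0.0

    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=2.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_full_overlap_matches_reference_equations(self, X, Y, a):
        """The niche-overlap generalization at c=1 is the base model."""
        p = ModelParams(a=a, c=1.0)
        got = rhs_xy(X, Y, p)
        gx = (Y + a) / (Y + a + p.kappa)
        gy = (p.beta * X + a) / (p.beta * X + a + p.kappa)
        ref = (
            p.r_x * X * gx * (1 - X - Y) - p.delta * X,
            p.r_y * Y * gy * (1 - X - Y) - p.delta * Y,
        )
        assert got == ref  # bit-identical, not just close


class TestMonoculture:
    def test_closed_form_equilibrium(self, default_params):
        assert monoculture_equilibrium(
            default_params.replace(a=0.48), "x"
        ) == pytest.approx(0.375, abs=1e-12)
        # threshold case: growth exactly balances death
        assert monoculture_equilibrium(default_params.replace(a=0.12), "x") == 0.0
        # no death: full carrying capacity for any positive supplementation
        assert monoculture_equilibrium(
            default_params.replace(a=0.03, delta=0.0), "y"
        ) == 1.0

    def test_no_nutrient_returns_zero_not_error(self, default_params):
        assert monoculture_equilibrium(default_params, "x") == 0.0

    def test_viability_thresholds(self, default_params):
        a_x = monoculture_viability_threshold(default_params, "x")
        a_y = monoculture_viability_threshold(default_params, "y")
        assert a_x == pytest.approx(0.12, abs=1e-12)
        assert a_y == pytest.approx(0.06 / 0.425, abs=1e-12)
        assert monoculture_viability_threshold(
            default_params.replace(delta=0.0), "x"
        ) == 0.0

    def test_threshold_requires_growth_exceeding_death(self, default_params):
        with pytest.raises(NoThresholdError):
            monoculture_viability_threshold(default_params.replace(delta=2.0), "x")

    @pytest.mark.parametrize("strain", ["x", "y"])
    @pytest.mark.parametrize("eps", [-1e-6, 1e-6])
    def test_equilibrium_switches_exactly_at_threshold(
        self, default_params, strain, eps
    ):
        a_c = monoculture_viability_threshold(default_params, strain)
        eq = monoculture_equilibrium(default_params.replace(a=a_c + eps), strain)
        assert (eq > 0) == (eps > 0)


class TestConcentrationMapping:
    @pytest.mark.parametrize("trp, scale, expected",
                             [(0.0, 0.1, 0.0), (1.0, 0.1, 0.1), (8.0, 0.1, 0.8)])
    def test_linear(self, trp, scale, expected):
        assert map_concentration_to_a(trp, scale) == pytest.approx(expected)

    def test_rejects_negative(self):
        with pytest.raises(InvalidParameterError):
            map_concentration_to_a(-1.0)


class TestTypes:
    def test_params_defaults_and_validation(self):
        p = ModelParams()
        assert (p.r_x, p.r_y, p.kappa, p.beta, p.delta) == (1.0, 0.925, 0.12, 2.0, 0.5)
        with pytest.raises(InvalidParameterError):
            ModelParams(kappa=-1)
        with pytest.raises(InvalidParameterError):
            ModelParams(c=1.5)

    def test_config_round_trip_and_unknown_key_rejection(self, tmp_path):
        p = ModelParams(a=0.23, c=0.8)
        for name in ("p.yaml", "p.json"):
            path = tmp_path / name
            p.to_file(path)
            assert ModelParams.from_file(path) == p
        with pytest.raises(InvalidParameterError, match="growth_rate"):
            ModelParams.from_dict({"r_x": 1.0, "growth_rate": 2.0})

    def test_population_state_derived_quantities(self):
        s = PopulationState(0.3, 0.1)
        assert s.n == pytest.approx(0.4)
        assert s.f == pytest.approx(3.0)
        assert math.isnan(PopulationState(0.3, 0.0).f)
        with pytest.raises(InvalidParameterError):
            PopulationState(-0.1, 0.2)

    def test_from_nf_inverts_n_and_f(self):
        s = PopulationState.from_nf(0.4, 3.0)
        assert s.n == pytest.approx(0.4)
        assert s.f == pytest.approx(3.0)
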