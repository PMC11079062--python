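import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from udsnet.model_core import (ModelParams, response,
                               drift, nullclines, fixed_points,
                               regime_diagnostics, _jacobian_EI)


class TestResponse:
    @pytest.mark.parametrize("x, g, th, expected", [
        (0.0517, 6.0, 0.0517, 0.0),            # exactly at threshold
        (0.0517 + 1 / 6, 6.0, 0.0517, 1.0),    # saturation knee
        (0.0517 + 1 / 12, 6.0, 0.0517, 0.5),   # linear midpoint
        (-5.0, 6.0, 0.0517, 0.0),
        (5.0, 6.0, 0.0517, 1.0),
    ])
    def test_threshold_linear_values(self, x, g, th, expected):
        assert response(x, g, th) == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonfinite_input(self):
        with pytest.raises(ValueError):
            response(np.nan, 6.0, 0.0517)
        with pytest.raises(ValueError):
            response(np.inf, 6.0, 0.0517)

    def test_rejects_nonpositive_gain(self):
        with pytest.raises(ValueError):
            response(0.1, 0.0, 0.0517)

    @settings(max_examples=200, deadline=None)
    @given(x=st.floats(-10, 10), dx=st.floats(0, 1),
           g=st.floats(0.1, 50), th=st.floats(-1, 1))
    def test_monotone_and_bounded(self, x, dx, g, th):
        y0, y1 = response(x, g, th), response(x + dx, g, th)
        assert 0.0 <= y0 <= 1.0
        assert y1 >= y0

    def test_vectorized(self):
        x = np.linspace(-1, 1, 101)
        y = response(x, 6.0, 0.0517)
        assert y.shape == x.shape
        assert np.all(np.diff(y) >= 0)


class TestDrift:
    def test_down_state_is_fixed_point(self, default_params):
        assert drift((0.0, 0.0, 0.0), default_params) == (0.0, 0.0, 0.0)

    def test_adapted_up_point_is_stationary(self, default_params):
        rep = fixed_points(default_params, adaptation_mode="self-consistent")
        E, I = rep.up
        A = default_params.W_AE * E
        d = drift((E, I, A), default_params)
        assert max(abs(v) for v in d) < 1e-12

    def test_adaptation_charging_rate(self, default_params):
        # at full excitatory activity with A=0, dA/dt = W_AE/tau_A per ms
        _, _, dA = drift((1.0, 0.3, 0.0), default_params)
        assert dA == pytest.approx(1.1 / 300.0)


class TestNullclines:
    def test_inhibitory_intercept(self, default_params):
        _, i_null = nullclines(0.0, default_params)
        assert i_null == pytest.approx(0.2778 / 1.66, rel=1e-12)

    def test_excitatory_intercept(self, default_params):
        e_null, _ = nullclines(0.0, default_params, A_star=0.0)
        assert e_null == pytest.approx(6 * 0.0517 / 5, rel=1e-12)

    def test_adaptation_shift_is_linear_and_uniform(self, default_params):
        I = np.linspace(0, 1, 7)
        e0, _ = nullclines(I, default_params, A_star=0.0)
        e1, _ = nullclines(I, default_params, A_star=0.1)
        shift = 6 * 0.166 * 0.1 / 5
        assert np.allclose(e1 - e0, shift, atol=1e-14)

    def test_degenerate_recurrence_raises(self, default_params):
        weak = default_params.with_(W_EE=1 / 6.0)
        with pytest.raises(ValueError, match="degenerate"):
            nullclines(0.0, weak)


class TestFixedPoints:
    def test_down_always_present(self, default_params):
        rep = fixed_points(default_params)
        assert rep.down == (0.0, 0.0)

    def test_up_point_reference_coordinates(self, default_params):
        rep = fixed_points(default_params, adaptation_mode="self-consistent")
        assert rep.up[0] == pytest.approx(0.2007, abs=1e-4)
        assert rep.up[1] == pytest.approx(0.4751, abs=1e-4)

    def test_up_point_matches_independent_root_finding(self, default_params):
        """Closed form vs bisection on the nullcline difference, 1e-10."""
        p = default_params
        rep = fixed_points(p, adaptation_mode="self-consistent",
                           check_numeric=False)

        def diff(I):
            E = ((1 + p.g_I * p.W_II) * I + p.g_I * p.theta_I) \
                / (p.g_I * p.W_IE)
            arg = (p.W_EE - p.W_EA * p.W_AE) * E - p.W_EI * I
            return -E + p.g_E * (arg - p.theta_E)

        I_star = brentq(diff, 1e-9, 1.0, xtol=1e-15)
        E_star = ((1 + p.g_I * p.W_II) * I_star + p.g_I * p.theta_I) \
            / (p.g_I * p.W_IE)
        assert abs(rep.up[0] - E_star) < 1e-10
        assert abs(rep.up[1] - I_star) < 1e-10

    def test_saddle_at_zero_adaptation(self, default_params):
        rep = fixed_points(default_params, adaptation_mode="frozen",
                           A_star=0.0)
        assert rep.saddle[0] == 0.0
        assert rep.saddle[1] == pytest.approx(0.06204, abs=1e-5)

    def test_adaptation_reduces_up_activity(self, default_params):
        """Rising A* shifts the excitatory nullcline up, lowering Up E."""
        prev = np.inf
        for a_star in (0.0, 0.1, 0.2, 0.3):
            rep = fixed_points(default_params, adaptation_mode="frozen",
                               A_star=a_star, check_numeric=False)
            assert rep.up[0] < prev
            prev = rep.up[0]

    def test_no_intersection_flagged_not_raised(self, default_params):
        # huge threshold pushes the excitatory nullcline above any crossing
        p = default_params.with_(theta_E=5.0)
        rep = fixed_points(p, check_numeric=False)
        assert rep.up is None

    def test_external_current_shifts_up_point_right(self, default_params):
        rep0 = fixed_points(default_params, check_numeric=False)
        rep1 = fixed_points(default_params, i_E=0.02, check_numeric=False)
        assert rep1.up[0] > rep0.up[0]


class TestRegimeDiagnostics:
    def test_classical_conditions_reported_verbatim(self, default_params):
        rep = regime_diagnostics(default_params)
        # threshold-ratio existence bound holds with a wide margin
        assert rep.condition_existence_threshold
        # gain bound has a negative right-hand side at these weights
        assert not rep.condition_existence_gain
        # determinant bound holds; the classical trace bound misses by ~0.3%
        assert rep.condition_determinant
        assert not rep.condition_trace

    def test_eigenvalues_decide_stability(self, default_params):
        rep = regime_diagnostics(default_params)
        assert rep.numerically_stable_up
        for lam in rep.jacobian_eigenvalues_up:
            assert lam.real < 0

    def test_jacobian_matches_finite_differences(self, default_params):
        p = default_params
        rep = fixed_points(p, check_numeric=False)
        E0, I0 = rep.up
        A0 = p.W_AE * E0
        J = _jacobian_EI(p)
        eps = 1e-7
        for col, d in enumerate([(eps, 0), (0, eps)]):
            f_plus = drift((E0 + d[0], I0 + d[1], A0), p)
            f_minus = drift((E0 - d[0], I0 - d[1], A0), p)
            fd = [(a - b) / (2 * eps) for a, b in zip(f_plus, f_minus)]
            assert fd[0] == pytest.approx(J[0, col], rel=1e-5)
            assert fd[1] == pytest.approx(J[1, col], rel=1e-5)


class TestModelParams:
    def test_json_round_trip(self, default_params):
        restored = ModelParams.from_json(default_params.to_json())
        assert restored == default_params

    @pytest.mark.parametrize("field, value", [
        ("tau_E", 0.0), ("g_I", -1.0), ("sigma_noise", -0.1),
        ("W_EE", -0.5), ("noise_tau", 0.0), ("noise_rho", 1.5),
    ])
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(ValueError):
            ModelParams(**{field: value})

    def test_defaults_carry_reference_constants(self, default_params):
        p = default_params
        assert (p.tau_E, p.tau_I, p.tau_A) == (10.0, 5.0, 300.0)
        assert (p.g_E, p.g_I) == (6.0, 30.0)
        assert (p.theta_E, p.theta_I) == (0.0517, 0.2778)
        assert (p.W_EE, p.W_II, p.W_EI, p.W_IE) == (1.0, 0.083, 0.166, 1.66)
        assert (p.W_EA, p.W_AE) == (0.166, 1.1)
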