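"""Rate law, closed-form and numeric integration, temperature profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stabkin.kinetics import (
    ArrheniusStep,
    KineticModel,
    KineticsError,
    TemperatureProfile,
    integrate_model_profile,
    integrate_step_isothermal,
    rate_constant,
    step_rate,
)

SEC_PER_DAY = 86400.0


class TestRateConstant:
    def test_printed_zero_order_rate_at_25C(self):
        k = rate_constant(ArrheniusStep(lnA=15.7, Ea=86600.0), 298.15)
        assert k == pytest.approx(4.42e-9, rel=1e-2)

    def test_zero_activation_energy_removes_T_dependence(self):
        step = ArrheniusStep(lnA=3.0, Ea=0.0)
        assert rate_constant(step, 278.15) == pytest.approx(np.exp(3.0), rel=1e-12)
        assert rate_constant(step, 313.15) == pytest.approx(np.exp(3.0), rel=1e-12)

    def test_monotone_in_temperature(self):
        step = ArrheniusStep(lnA=15.7, Ea=86600.0)
        assert rate_constant(step, 313.15) > rate_constant(step, 278.15)

    @pytest.mark.parametrize("T", [0.0, -5.0, float("nan"), float("inf")])
    def test_invalid_temperature_rejected(self, T):
        with pytest.raises(KineticsError):
            rate_constant(ArrheniusStep(lnA=1.0, Ea=1000.0), T)


class TestStepRate:
    def test_vanishes_at_complete_conversion(self):
        step = ArrheniusStep(lnA=10.0, Ea=50e3, n=2.0)
        assert step_rate(step, 1.0, 300.0) == 0.0

    def test_zero_order_rate_is_alpha_independent(self):
        step = ArrheniusStep(lnA=10.0, Ea=50e3)
        k = rate_constant(step, 300.0)
        for alpha in (0.0, 0.3, 0.9):
            assert step_rate(step, alpha, 300.0) == pytest.approx(k, rel=1e-12)

    def test_printed_autocatalytic_rate_at_40C(self):
        step = ArrheniusStep(lnA=16.1, Ea=85800.0, n=4.0, m=0.2)
        assert step_rate(step, 0.1, 313.15) == pytest.approx(1.98e-8, rel=1e-2)

    def test_alpha_outside_unit_interval_rejected(self):
        step = ArrheniusStep(lnA=10.0, Ea=50e3)
        with pytest.raises(KineticsError):
            step_rate(step, 1.2, 300.0)


class TestStepValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lnA": 1.0, "Ea": -5.0},
            {"lnA": 1.0, "Ea": 1e3, "n": 12.0},
            {"lnA": 1.0, "Ea": 1e3, "m": 3.0},
            {"lnA": float("nan"), "Ea": 1e3},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(KineticsError):
            ArrheniusStep(**kwargs)

    def test_one_step_model_requires_unit_weight(self):
        with pytest.raises(KineticsError):
            KineticModel(steps=(ArrheniusStep(1.0, 1e3),), weights=(0.9,))

    def test_two_step_weights_must_sum_to_one(self):
        s = ArrheniusStep(1.0, 1e3)
        with pytest.raises(KineticsError):
            KineticModel(steps=(s, s), weights=(0.6, 0.3))


class TestIsothermalIntegration:
    def test_zero_order_closed_form_90d(self):
        # k = 1e-8 1/s: alpha(90 d) = k * 90 * 86400 = 0.07776
        step = ArrheniusStep(lnA=np.log(1e-8), Ea=0.0)
        alpha = integrate_step_isothermal(step, 300.0, 0.0, [90.0])
        assert alpha[-1] == pytest.approx(0.0778, abs=1e-4)

    def test_first_order_saturates_to_one(self):
        step = ArrheniusStep(lnA=0.0, Ea=0.0, n=1.0)  # k = 1/s, huge k*t
        alpha = integrate_step_isothermal(step, 300.0, 0.0, [10.0])
        assert alpha[-1] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n", [0.0, 1.0])
    def test_numeric_matches_closed_form(self, n):
        step = ArrheniusStep(lnA=15.7, Ea=86600.0, n=n)
        times = np.linspace(0.0, 90.0, 13)
        closed = integrate_step_isothermal(step, 313.15, 0.0, times)
        numeric = integrate_step_isothermal(step, 313.15, 0.0, times, method="ode")
        np.testing.assert_allclose(numeric, closed, atol=1e-6)

    def test_decreasing_times_rejected(self):
        step = ArrheniusStep(lnA=10.0, Ea=50e3)
        with pytest.raises(KineticsError):
            integrate_step_isothermal(step, 300.0, 0.0, [10.0, 5.0])

    @given(
        n=st.floats(0.0, 6.0),
        m=st.floats(0.0, 1.0),
        lnA=st.floats(5.0, 20.0),
        ea_kj=st.floats(40.0, 120.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_trajectories_bounded_and_nondecreasing(self, n, m, lnA, ea_kj):
        step = ArrheniusStep(lnA=lnA, Ea=ea_kj * 1e3, n=n, m=m)
        times = np.linspace(0.0, 90.0, 10)
        alpha = integrate_step_isothermal(step, 313.15, 0.0, times)
        assert np.all(alpha >= 0.0) and np.all(alpha <= 1.0)
        assert np.all(np.diff(alpha) >= 0.0)


def rk4_oracle(model, T, t_end_days, dt_days=0.01, alpha_seed=1e-8):
    """Fixed-step classical RK4 on the full weighted system (oracle)."""
    n_steps_int = int(round(t_end_days / dt_days))
    h = dt_days * SEC_PER_DAY
    k = np.array([rate_constant(s, T) for s in model.steps])
    n = np.array([s.n for s in model.steps])
    m = np.array([s.m for s in model.steps])

    def f(a):
        a = np.clip(a, 0.0, 1.0)
        return k * (1.0 - a) ** n * np.maximum(a, alpha_seed) ** m

    a = np.zeros(len(model.steps))
    for _ in range(n_steps_int):
        k1 = f(a)
        k2 = f(a + 0.5 * h * k1)
        k3 = f(a + 0.5 * h * k2)
        k4 = f(a + h * k3)
        a = np.clip(a + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0, 1.0)
    return float(np.dot(model.weights, a))


class TestProfileIntegration:
    def test_single_segment_reduces_to_isothermal(self):
        model = KineticModel.one_step(15.7, 86600.0, n=1.0)
        times = np.array([0.0, 30.0, 90.0])
        profile = TemperatureProfile.isothermal(313.15, 90.0)
        traj = integrate_model_profile(model, profile, times)
        iso = integrate_step_isothermal(model.steps[0], 313.15, 0.0, times)
        np.testing.assert_allclose(traj.overall, iso, atol=1e-12)

    def test_storage_plus_excursion_zero_order_additivity(self):
        # two years at 5 degC then 28 days at 30 degC; zero-order progress adds
        model = KineticModel.one_step(15.7, 86600.0)
        profile = TemperatureProfile.from_string("730d@5C,28d@30C")
        traj = integrate_model_profile(model, profile, [730.0, 758.0])
        assert traj.overall[0] == pytest.approx(0.0226, abs=2e-4)
        assert traj.overall[-1] == pytest.approx(0.0417, abs=3e-4)

    def test_degenerate_two_step_weight_matches_one_step(self):
        s1 = ArrheniusStep(15.7, 86600.0)
        s2 = ArrheniusStep(4.0, 48200.0, n=0.5)
        # w1 -> 1 within the weight invariant; compare against pure step 1
        two = KineticModel(steps=(s1, s2), weights=(1.0 - 1e-12, 1e-12))
        one = KineticModel.one_step(15.7, 86600.0)
        times = np.linspace(0.0, 400.0, 6)
        profile = TemperatureProfile.isothermal(303.15, 400.0)
        t2 = integrate_model_profile(two, profile, times)
        t1 = integrate_model_profile(one, profile, times)
        np.testing.assert_allclose(t2.overall, t1.overall, atol=1e-9)

    def test_grid_beyond_profile_rejected(self):
        model = KineticModel.one_step(15.7, 86600.0)
        profile = TemperatureProfile.isothermal(278.15, 100.0)
        with pytest.raises(KineticsError):
            integrate_model_profile(model, profile, [150.0])

    def test_splitting_a_segment_leaves_trajectory_unchanged(self, all_fixtures):
        model = all_fixtures[0].model
        whole = TemperatureProfile(((60.0, 310.15),))
        halves = TemperatureProfile(((30.0, 310.15), (30.0, 310.15)))
        grid = np.array([0.0, 15.0, 30.0, 45.0, 60.0])
        a = integrate_model_profile(model, whole, grid).overall
        b = integrate_model_profile(model, halves, grid).overall
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_adaptive_integration_matches_rk4_oracle_all_models(self, all_fixtures):
        # every printed model, 90 days at 40 degC, fixed-step RK4 at 0.01 d
        for truth in all_fixtures:
            expected = rk4_oracle(truth.model, 313.15, 90.0)
            traj = integrate_model_profile(
                truth.model, TemperatureProfile.isothermal(313.15, 90.0), [90.0]
            )
            assert traj.overall[-1] == pytest.approx(expected, abs=1e-6), truth.name


class TestTemperatureProfile:
    def test_profile_string_round_trip(self):
        profile = TemperatureProfile.from_string("730d@5C,28d@30C")
        assert profile.segments == ((730.0, 278.15), (28.0, 303.15))
        assert profile.total_days == 758.0
        assert TemperatureProfile.from_string(profile.to_string()) == profile

    def test_hours_unit(self):
        profile = TemperatureProfile.from_string("12h@25C")
        assert profile.segments[0][0] == pytest.approx(0.5)

    @pytest.mark.parametrize("bad", ["", "30@5C", "10d@5K", "-3d@5C"])
    def test_malformed_profile_strings_rejected(self, bad):
        with pytest.raises(KineticsError):
            TemperatureProfile.from_string(bad)
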