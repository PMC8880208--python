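"""Long-term prediction, bootstrap bands, shelf life, accuracy tables."""

import numpy as np
import pytest

from stabkin.datamodel import AttributeMap
from stabkin.fitting import FitCandidate, StepSpec, fit_candidate
from stabkin.kinetics import TemperatureProfile
from stabkin.prediction import (
    PredictionError,
    PredictionScenario,
    accuracy_table,
    bootstrap_prediction_interval,
    predict_trajectory,
    shelf_life_estimate,
)
from stabkin.synthetic import StudyDesign, simulate_study

ZERO_ORDER = FitCandidate("1step_n0", (StepSpec(n=0.0, m=0.0),))
PURITY_MAP = AttributeMap.for_purity(y0=98.1, delta_max=-100.0)


@pytest.fixture(scope="module")
def zero_order_fit(noiseless_zero_order_dataset):
    return fit_candidate(noiseless_zero_order_dataset, ZERO_ORDER, PURITY_MAP, n_starts=4, seed=3)


@pytest.fixture(scope="module")
def noisy_result(noisy_zero_order_dataset, storage_scenario):
    fit = fit_candidate(noisy_zero_order_dataset, ZERO_ORDER, PURITY_MAP, n_starts=4, seed=3)
    result = bootstrap_prediction_interval(
        noisy_zero_order_dataset, fit, storage_scenario, seed=5
    )
    return fit, result


@pytest.fixture(scope="module")
def storage_scenario():
    profile = TemperatureProfile.from_string("730d@5C,28d@30C")
    return PredictionScenario(
        profile=profile, evaluation_times=(0.0, 365.0, 730.0, 758.0), pi_level=99.9, n_boot=200
    )


class TestPredictTrajectory:
    def test_starts_at_y0(self, zero_order_fit, storage_scenario):
        values = predict_trajectory(zero_order_fit, storage_scenario)
        assert values[0] == pytest.approx(98.1, abs=1e-6)

    def test_two_year_purity_from_printed_zero_order_model(self, zero_order_fit, storage_scenario):
        values = predict_trajectory(zero_order_fit, storage_scenario)
        assert values[2] == pytest.approx(95.84, abs=0.02)

    def test_zero_order_attribute_linear_in_time(self, zero_order_fit):
        profile = TemperatureProfile.isothermal(298.15, 100.0)
        scenario = PredictionScenario(
            profile=profile, evaluation_times=tuple(np.linspace(0, 100, 11)), n_boot=200
        )
        values = predict_trajectory(zero_order_fit, scenario)
        slopes = np.diff(values) / 10.0
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-9)

    def test_profile_composability(self, zero_order_fit):
        # prediction through the combined profile equals continuing from the
        # state reached at the end of storage
        from stabkin.kinetics import integrate_model_profile

        model = zero_order_fit.model
        full = integrate_model_profile(
            model, TemperatureProfile.from_string("730d@5C,28d@30C"), [758.0]
        )
        stage1 = integrate_model_profile(
            model, TemperatureProfile.isothermal(278.15, 730.0), [730.0]
        )
        state = stage1.state_at_end(model)
        stage2 = integrate_model_profile(
            model,
            TemperatureProfile.isothermal(303.15, 28.0),
            [28.0],
            state0=state,
        )
        assert stage2.overall[-1] == pytest.approx(full.overall[-1], abs=1e-9)

    def test_evaluation_beyond_profile_rejected(self, storage_scenario):
        with pytest.raises(PredictionError):
            PredictionScenario(
                profile=storage_scenario.profile,
                evaluation_times=(800.0,),
                n_boot=200,
            )


class TestBootstrapPI:
    def test_noiseless_band_width_is_zero(
        self, noiseless_zero_order_dataset, zero_order_fit, storage_scenario
    ):
        result = bootstrap_prediction_interval(
            noiseless_zero_order_dataset, zero_order_fit, storage_scenario, seed=5
        )
        assert np.all(result.upper - result.lower < 1e-9)

    def test_band_floor_on_resamples(self, zero_order_purity_truth, storage_scenario):
        with pytest.raises(PredictionError):
            PredictionScenario(
                profile=storage_scenario.profile,
                evaluation_times=(730.0,),
                n_boot=50,
            )

    def test_band_brackets_mean_and_truth(self, noisy_result, zero_order_purity_truth):
        from stabkin.kinetics import integrate_model_profile
        from stabkin.datamodel import attribute_from_alpha

        fit, result = noisy_result
        assert np.all(result.lower <= result.mean + 1e-12)
        assert np.all(result.mean <= result.upper + 1e-12)
        truth_traj = integrate_model_profile(
            zero_order_purity_truth.model,
            result.scenario.profile,
            np.asarray(result.times_days),
        )
        truth_vals = attribute_from_alpha(zero_order_purity_truth.amap, truth_traj.overall)
        covered = (result.lower <= truth_vals) & (truth_vals <= result.upper)
        assert covered.mean() >= 0.95

    def test_wider_level_encloses_narrower(self, noisy_zero_order_dataset, storage_scenario):
        fit = fit_candidate(noisy_zero_order_dataset, ZERO_ORDER, PURITY_MAP, n_starts=4, seed=3)
        wide = bootstrap_prediction_interval(
            noisy_zero_order_dataset, fit, storage_scenario, seed=5
        )
        narrow_scenario = PredictionScenario(
            profile=storage_scenario.profile,
            evaluation_times=storage_scenario.evaluation_times,
            pi_level=95.0,
            n_boot=200,
        )
        narrow = bootstrap_prediction_interval(
            noisy_zero_order_dataset, fit, narrow_scenario, seed=5
        )
        assert np.all(wide.lower <= narrow.lower + 1e-12)
        assert np.all(narrow.upper <= wide.upper + 1e-12)

    def test_deterministic_given_seed(self, noisy_zero_order_dataset, storage_scenario):
        fit = fit_candidate(noisy_zero_order_dataset, ZERO_ORDER, PURITY_MAP, n_starts=4, seed=3)
        r1 = bootstrap_prediction_interval(noisy_zero_order_dataset, fit, storage_scenario, seed=5)
        r2 = bootstrap_prediction_interval(noisy_zero_order_dataset, fit, storage_scenario, seed=5)
        np.testing.assert_array_equal(r1.lower, r2.lower)
        np.testing.assert_array_equal(r1.upper, r2.upper)


class TestShelfLife:
    def test_zero_order_crossing_time(self):
        # k = 1e-8 1/s, 2-point purity drop: t = 0.02 / k = 2e6 s = 23.15 d
        from stabkin.fitting import FitResult
        from stabkin.kinetics import KineticModel

        model = KineticModel.one_step(np.log(1e-8), 0.0)
        truth_map = AttributeMap.for_purity(y0=98.1, delta_max=-100.0)
        fit = FitResult(
            candidate=ZERO_ORDER,
            model=model,
            amap=truth_map,
            rss=0.0,
            n_obs=30,
            n_params=2,
            converged=True,
            multistart_trace=(0.0,),
            seed=0,
            x=(float(np.log(1e-8)), 0.0),
        )
        res = shelf_life_estimate(fit, 300.0, 98.1 - 2.0)
        assert res.crossed
        assert res.time_days == pytest.approx(23.148, abs=0.01)

    def test_saturating_process_beyond_horizon(self, two_step_hmwp_truth):
        # HMWP plateau far below a generous limit: no crossing within 5 years
        ds = simulate_study(StudyDesign(noise_sd=0.0), two_step_hmwp_truth)
        cand = FitCandidate("2step", (StepSpec(n=0.0, m=0.0), StepSpec(n=0.5, m=0.0)))
        fit = fit_candidate(ds, cand, two_step_hmwp_truth.amap, n_starts=8, seed=3)
        res = shelf_life_estimate(fit, 278.15, 10.0)
        assert res.status == "beyond_horizon"
        assert res.time_days is None

    def test_lower_temperature_gives_longer_shelf_life(self, zero_order_fit):
        warm = shelf_life_estimate(zero_order_fit, 303.15, 96.0)
        cold = shelf_life_estimate(zero_order_fit, 278.15, 96.0)
        assert warm.crossed
        assert cold.status == "beyond_horizon" or cold.time_days > warm.time_days

    def test_already_violated_limit_flags_immediate_failure(self, zero_order_fit):
        res = shelf_life_estimate(zero_order_fit, 278.15, 99.0)
        assert res.status == "immediate_failure"
        assert res.time_days == 0.0


class TestAccuracyTable:
    def test_published_purity_row(self):
        table = accuracy_table({"Combi_F1-PM1": 96.1}, {"Combi_F1-PM1": 95.3})
        assert table.loc["Combi_F1-PM1", "delta"] == pytest.approx(0.8)

    def test_published_hmwp_row(self):
        table = accuracy_table({"Combi_F1-PM1": 0.82}, {"Combi_F1-PM1": 0.84})
        assert table.loc["Combi_F1-PM1", "delta"] == pytest.approx(-0.02)

    def test_equal_values_give_zero_delta_and_max(self):
        table = accuracy_table({"a": 95.0, "b": 96.0}, {"a": 95.0, "b": 96.0})
        assert (table["delta"] == 0).all()
        assert table.attrs["max_abs_delta"] == 0.0

    def test_mismatched_labels_rejected(self):
        with pytest.raises(PredictionError, match="align"):
            accuracy_table({"a": 1.0}, {"b": 1.0})
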