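"""Long-term predictions, bootstrap prediction intervals, shelf life.

A fitted model is extrapolated over a storage temperature profile (e.g. two
years refrigerated plus a 28-day in-use excursion at 30 degC).  Uncertainty
bands are residual-bootstrap percentile prediction intervals: fitted
residuals are resampled with replacement onto the fitted values, the model is
refitted to each pseudo-dataset, re-predicted, and two-sided symmetric
percentiles of the replicate predictions form the band.  Residual (rather
than case) resampling is used because single-point accelerated designs leave
no replicates to resample within design cells.  The band therefore reflects
fitted-parameter uncertainty, not future observation noise.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datamodel import StabilityDataset, attribute_from_alpha
from .fitting import FitResult, predict_dataset_values, prediction_leverages, refit_like
from .kinetics import TemperatureProfile, integrate_model_profile

__all__ = [
    "PredictionScenario",
    "PredictionResult",
    "ShelfLifeResult",
    "predict_trajectory",
    "bootstrap_prediction_interval",
    "shelf_life_estimate",
    "accuracy_table",
    "PredictionError",
]

log = logging.getLogger(__name__)

DEFAULT_HORIZON_DAYS = 5 * 365.25


class PredictionError(ValueError):
    """Invalid prediction scenario or inputs."""


@dataclass(frozen=True)
class PredictionScenario:
    """A storage/in-use scenario: profile, output times, PI settings."""

    profile: TemperatureProfile
    evaluation_times: tuple[float, ...]
    pi_level: float = 99.9
    n_boot: int = 200

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.evaluation_times)
        if not times or any(t < 0 for t in times) or any(
            b < a for a, b in zip(times, times[1:])
        ):
            raise PredictionError("evaluation times must be non-negative and non-decreasing")
        if times[-1] > self.profile.total_days * (1 + 1e-12):
            raise PredictionError(
                f"evaluation time {times[-1]} d beyond profile end "
                f"({self.profile.total_days} d)"
            )
        if not 50.0 < self.pi_level < 100.0:
            raise PredictionError("pi_level must be in (50, 100)")
        if self.n_boot <= 100:
            raise PredictionError("n_boot must exceed 100 resamples")
        object.__setattr__(self, "evaluation_times", times)


@dataclass(frozen=True)
class PredictionResult:
    """Predicted trajectory with a percentile prediction band."""

    times_days: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    scenario: PredictionScenario
    seed: int | None = None
    n_boot_failed: int = 0
    warnings: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_days": self.times_days,
                "mean": self.mean,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def predict_trajectory(fit: FitResult, scenario: PredictionScenario, **int_kwargs) -> np.ndarray:
    """Deterministic attribute trajectory of the fitted model over the
    scenario profile, at the scenario's evaluation times."""
    traj = integrate_model_profile(
        fit.model, scenario.profile, np.asarray(scenario.evaluation_times), **int_kwargs
    )
    return attribute_from_alpha(fit.amap, traj.overall)


def bootstrap_prediction_interval(
    dataset: StabilityDataset,
    fit: FitResult,
    scenario: PredictionScenario,
    seed: int = 0,
    *,
    refit_starts: int = 1,
) -> PredictionResult:
    """Residual-bootstrap percentile prediction interval.

    The resampling pool uses leverage-adjusted, centered residuals
    ``r_i / sqrt(1 - h_ii)`` (Gauss-Newton hat diagonal), since raw fitted
    residuals underestimate the observation noise and would deflate the band.
    The band at level L spans the (100-L)/2 and 100-(100-L)/2 percentiles of
    the ``n_boot`` replicate predictions; refits are warm-started at the
    original optimum.  Deterministic given ``seed``.
    """
    fitted = predict_dataset_values(fit.model, fit.amap, dataset)
    observed = dataset.frame["value"].to_numpy()
    raw = observed - fitted
    try:
        h = prediction_leverages(fit, dataset)
        residuals = raw / np.sqrt(1.0 - h)
    except Exception:  # ill-conditioned Jacobian: global d.o.f. factor
        residuals = raw * np.sqrt(fit.n_obs / max(1, fit.n_obs - fit.n_params))
    residuals = residuals - residuals.mean()

    rng = np.random.default_rng(seed)
    times = np.asarray(scenario.evaluation_times)
    boot_preds = np.empty((scenario.n_boot, times.size))
    n_failed = 0
    for b in range(scenario.n_boot):
        resampled = fitted + rng.choice(residuals, size=residuals.size, replace=True)
        try:
            boot_fit = refit_like(fit, dataset.with_values(resampled), n_starts=refit_starts)
            boot_preds[b] = predict_trajectory(boot_fit, scenario)
        except Exception as exc:  # refit failure: reuse the point prediction
            log.debug("bootstrap replicate %d failed: %s", b, exc)
            boot_preds[b] = predict_trajectory(fit, scenario)
            n_failed += 1

    warnings: tuple[str, ...] = ()
    if n_failed > 0.1 * scenario.n_boot:
        msg = f"{n_failed}/{scenario.n_boot} bootstrap refits failed; band may be too narrow"
        _warnings.warn(msg, stacklevel=2)
        warnings = (msg,)

    q_lo = (100.0 - scenario.pi_level) / 2.0
    lower = np.percentile(boot_preds, q_lo, axis=0)
    upper = np.percentile(boot_preds, 100.0 - q_lo, axis=0)
    mean = predict_trajectory(fit, scenario)
    return PredictionResult(
        times_days=times,
        mean=mean,
        lower=np.minimum(lower, mean),
        upper=np.maximum(upper, mean),
        scenario=scenario,
        seed=seed,
        n_boot_failed=n_failed,
        warnings=warnings,
    )


@dataclass(frozen=True)
class ShelfLifeResult:
    """Time to specification crossing at constant storage temperature."""

    status: str  # "crossed" | "beyond_horizon" | "immediate_failure"
    time_days: float | None
    spec_limit: float
    temperature_K: float

    @property
    def crossed(self) -> bool:
        return self.status == "crossed"


def shelf_life_estimate(
    fit: FitResult,
    T: float,
    spec_limit: float,
    *,
    horizon_days: float = DEFAULT_HORIZON_DAYS,
    **int_kwargs,
) -> ShelfLifeResult:
    """Earliest time the predicted attribute crosses ``spec_limit`` at
    constant temperature ``T``.

    Crossing is located on a 1-day grid and refined by bisection to 1e-3
    days.  Returns ``beyond_horizon`` when no crossing occurs before
    ``horizon_days`` (default five years).
    """
    amap = fit.amap
    falling = amap.delta_max < 0

    def attr_at(t_days: float) -> float:
        traj = integrate_model_profile(
            fit.model,
            TemperatureProfile.isothermal(T, max(horizon_days, t_days) + 1.0),
            np.array([t_days]),
            **int_kwargs,
        )
        return float(attribute_from_alpha(amap, traj.overall)[-1])

    def violated(value: float) -> bool:
        return value <= spec_limit if falling else value >= spec_limit

    if violated(amap.y0):
        return ShelfLifeResult("immediate_failure", 0.0, spec_limit, T)

    grid = np.arange(0.0, horizon_days + 1.0, 1.0)
    profile = TemperatureProfile.isothermal(T, horizon_days + 1.0)
    traj = integrate_model_profile(fit.model, profile, grid, **int_kwargs)
    values = attribute_from_alpha(amap, traj.overall)
    hit = np.nonzero([violated(v) for v in values])[0]
    if hit.size == 0:
        return ShelfLifeResult("beyond_horizon", None, spec_limit, T)
    i = int(hit[0])
    if i == 0:
        return ShelfLifeResult("crossed", 0.0, spec_limit, T)
    t_cross = brentq(
        lambda t: attr_at(t) - spec_limit, grid[i - 1], grid[i], xtol=1e-3
    )
    return ShelfLifeResult("crossed", float(t_cross), spec_limit, T)


def accuracy_table(predicted, experimental) -> pd.DataFrame:
    """Prediction-accuracy table: Delta = predicted - experimental, in
    percentage points, per product, plus the maximum absolute deviation
    stored in ``DataFrame.attrs['max_abs_delta']``.

    ``predicted`` and ``experimental`` are mappings or Series keyed by
    product label; the labels must match exactly.
    """
    pred = pd.Series(predicted, dtype=float)
    exp = pd.Series(experimental, dtype=float)
    if set(pred.index) != set(exp.index):
        only_p = sorted(set(pred.index) - set(exp.index))
        only_e = sorted(set(exp.index) - set(pred.index))
        raise PredictionError(
            f"product labels do not align (only predicted: {only_p}, only experimental: {only_e})"
        )
    exp = exp.reindex(pred.index)
    out = pd.DataFrame(
        {"experimental": exp, "predicted": pred, "delta": pred - exp}
    )
    out.attrs["max_abs_delta"] = float(out["delta"].abs().max())
    return out
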