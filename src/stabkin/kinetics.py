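"""Kinetic model family and reaction-progress integration.

The degradation of a drug-product attribute is described by the normalized
reaction progress ``alpha`` (0 = intact, 1 = fully degraded on the attribute's
own scale), evolving under an nth-order, possibly autocatalytic rate law with
Arrhenius temperature dependence::

    d(alpha)/dt = exp(lnA) * exp(-Ea / (R*T)) * (1 - alpha)**n * alpha**m

A measured attribute may be driven by one such sub-process, or by the weighted
sum of two independent sub-processes (``alpha = w1*alpha1 + w2*alpha2``), which
captures bi-phasic behavior such as a fast initial aggregation step on top of a
slow high-activation-energy pathway.

Rates are expressed per second internally; all times at the API surface are in
days.  Temperatures are Kelvin throughout.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "R_GAS",
    "SECONDS_PER_DAY",
    "DEFAULT_ALPHA_SEED",
    "ArrheniusStep",
    "KineticModel",
    "TemperatureProfile",
    "ProgressState",
    "ProgressTrajectory",
    "rate_constant",
    "step_rate",
    "integrate_step_isothermal",
    "integrate_model_isothermal",
    "integrate_model_profile",
    "KineticsError",
    "IntegrationError",
]

#: Universal gas constant, J mol^-1 K^-1.
R_GAS = 8.314

SECONDS_PER_DAY = 86400.0

#: Floor applied to the autocatalytic factor alpha**m so that trajectories
#: starting at exactly alpha=0 are not frozen at the alpha=0 fixed point.
#: Numerically negligible everywhere else (1e-8**m <= 1 for m >= 0).
DEFAULT_ALPHA_SEED = 1e-8

#: Physically plausible temperature window for stability studies, Kelvin.
TEMPERATURE_RANGE_K = (233.0, 373.0)


class KineticsError(ValueError):
    """Invalid kinetic parameter, temperature, or progress value."""


class IntegrationError(RuntimeError):
    """The adaptive integrator failed; message carries diagnostics."""


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise KineticsError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ArrheniusStep:
    """One Arrhenius-activated sub-process of the rate law.

    Parameters
    ----------
    lnA
        Natural log of the pre-exponential factor; the rate constant carries
        units of 1/s.
    Ea
        Activation energy in J/mol (>= 0).
    n
        Reaction order on the remaining fraction ``(1-alpha)``; 0 <= n <= 10.
    m
        Autocatalytic exponent on ``alpha``; 0 <= m <= 2.  m > 0 yields
        S-shaped (self-accelerating) progress curves.
    """

    lnA: float
    Ea: float
    n: float = 0.0
    m: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lnA", "Ea", "n", "m"):
            _require_finite(name, getattr(self, name))
        if self.Ea < 0:
            raise KineticsError(f"Ea must be >= 0, got {self.Ea}")
        if not 0.0 <= self.n <= 10.0:
            raise KineticsError(f"reaction order n must be in [0, 10], got {self.n}")
        if not 0.0 <= self.m <= 2.0:
            raise KineticsError(f"autocatalytic exponent m must be in [0, 2], got {self.m}")


@dataclass(frozen=True)
class KineticModel:
    """One- or two-step kinetic model: weighted independent sub-processes.

    The overall progress is ``alpha = sum_i w_i * alpha_i`` with each
    sub-progress ``alpha_i`` integrated under its own rate law.  Weights are
    positive and sum to one; a one-step model has the single weight 1.
    """

    steps: tuple[ArrheniusStep, ...]
    weights: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        steps = tuple(self.steps)
        object.__setattr__(self, "steps", steps)
        if not 1 <= len(steps) <= 2:
            raise KineticsError(f"a model has 1 or 2 steps, got {len(steps)}")
        weights = tuple(float(w) for w in (self.weights or ()))
        if not weights:
            weights = (1.0,) if len(steps) == 1 else ()
        if len(weights) != len(steps):
            raise KineticsError("one weight per step is required")
        if len(steps) == 1 and weights[0] != 1.0:
            raise KineticsError("a one-step model must have weight exactly 1")
        for w in weights:
            if not (0.0 < w <= 1.0) or not math.isfinite(w):
                raise KineticsError(f"weights must be in (0, 1], got {w}")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise KineticsError(f"weights must sum to 1, got {sum(weights)}")
        object.__setattr__(self, "weights", weights)

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @classmethod
    def one_step(cls, lnA: float, Ea: float, n: float = 0.0, m: float = 0.0) -> "KineticModel":
        return cls(steps=(ArrheniusStep(lnA, Ea, n, m),), weights=(1.0,))

    @classmethod
    def two_step(
        cls,
        w1: float,
        step1: ArrheniusStep,
        step2: ArrheniusStep,
    ) -> "KineticModel":
        return cls(steps=(step1, step2), weights=(float(w1), 1.0 - float(w1)))

    def make_state(self, sub_alphas: Sequence[float]) -> "ProgressState":
        sub = tuple(float(a) for a in sub_alphas)
        if len(sub) != self.n_steps:
            raise KineticsError("one sub-progress per step is required")
        overall = float(np.dot(self.weights, sub))
        return ProgressState(sub_alphas=sub, overall_alpha=overall)


@dataclass(frozen=True)
class ProgressState:
    """Per-step reaction progresses and their weighted overall value."""

    sub_alphas: tuple[float, ...]
    overall_alpha: float

    def __post_init__(self) -> None:
        for a in self.sub_alphas:
            if not 0.0 <= a <= 1.0:
                raise KineticsError(f"sub-progress must be in [0, 1], got {a}")
        if not 0.0 <= self.overall_alpha <= 1.0:
            raise KineticsError(f"overall progress must be in [0, 1], got {self.overall_alpha}")


@dataclass(frozen=True)
class TemperatureProfile:
    """Piecewise-constant time-temperature program.

    ``segments`` is an ordered list of ``(duration_days, temperature_K)``
    pairs, e.g. two years of refrigerated storage followed by a four-week
    in-use excursion at 30 degC is ``((730, 278.15), (28, 303.15))``.
    """

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        segs = tuple((float(d), float(T)) for d, T in self.segments)
        if not segs:
            raise KineticsError("a profile needs at least one segment")
        lo, hi = TEMPERATURE_RANGE_K
        for d, T in segs:
            if not (d > 0 and math.isfinite(d)):
                raise KineticsError(f"segment duration must be > 0 days, got {d}")
            if not (lo <= T <= hi):
                raise KineticsError(f"temperature {T} K outside plausible range [{lo}, {hi}] K")
        object.__setattr__(self, "segments", segs)

    @property
    def total_days(self) -> float:
        return sum(d for d, _ in self.segments)

    @classmethod
    def isothermal(cls, temperature_K: float, duration_days: float) -> "TemperatureProfile":
        return cls(((duration_days, temperature_K),))

    _SEGMENT_RE = re.compile(r"^\s*([0-9]*\.?[0-9]+)\s*([dh])\s*@\s*(-?[0-9]*\.?[0-9]+)\s*C\s*$")

    @classmethod
    def from_string(cls, spec: str) -> "TemperatureProfile":
        """Parse a profile string like ``"730d@5C,28d@30C"`` (d=days, h=hours)."""
        segments = []
        for part in spec.split(","):
            match = cls._SEGMENT_RE.match(part)
            if match is None:
                raise KineticsError(
                    f"cannot parse profile segment {part!r}; expected '<number><d|h>@<number>C'"
                )
            amount, unit, temp_c = match.groups()
            days = float(amount) / 24.0 if unit == "h" else float(amount)
            segments.append((days, float(temp_c) + 273.15))
        return cls(tuple(segments))

    def to_string(self) -> str:
        return ",".join(f"{d:g}d@{T - 273.15:g}C" for d, T in self.segments)


@dataclass(frozen=True)
class ProgressTrajectory:
    """Reaction-progress trajectory over a temperature profile."""

    times_days: np.ndarray
    sub_alphas: np.ndarray  # shape (n_steps, n_times)
    weights: tuple[float, ...]
    overall: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        overall = np.asarray(self.weights) @ self.sub_alphas
        object.__setattr__(self, "overall", overall)

    def state_at_end(self, model: KineticModel) -> ProgressState:
        return model.make_state(self.sub_alphas[:, -1])


def rate_constant(step: ArrheniusStep, T: float) -> float:
    """Arrhenius rate constant ``k = exp(lnA - Ea/(R*T))`` in 1/s."""
    T = float(T)
    if not (math.isfinite(T) and T > 0):
        raise KineticsError(f"temperature must be positive and finite, got {T!r}")
    return math.exp(step.lnA - step.Ea / (R_GAS * T))


def step_rate(
    step: ArrheniusStep,
    alpha: float,
    T: float,
    alpha_seed: float = DEFAULT_ALPHA_SEED,
) -> float:
    """Instantaneous rate ``d(alpha)/dt`` in 1/s at progress ``alpha``.

    The autocatalytic factor ``alpha**m`` is evaluated at
    ``max(alpha, alpha_seed)`` so a process starting at exactly zero progress
    can leave the fixed point.
    """
    alpha = float(alpha)
    if not 0.0 <= alpha <= 1.0:
        raise KineticsError(f"alpha must be in [0, 1], got {alpha}")
    k = rate_constant(step, T)
    rate = k * (1.0 - alpha) ** step.n
    if step.m > 0:
        rate *= max(alpha, alpha_seed) ** step.m
    return rate


def _power_law_closed_form(n: float, tau: np.ndarray, alpha0: float) -> np.ndarray:
    """alpha(tau) for m=0 in scaled time tau = k*t, any order n >= 0."""
    if n == 0.0:
        return np.minimum(1.0, alpha0 + tau)
    if n == 1.0:
        return 1.0 - (1.0 - alpha0) * np.exp(-tau)
    p = 1.0 - n
    g = (1.0 - alpha0) ** p - p * tau
    # n < 1: g hits zero at finite tau (complete conversion); n > 1: g grows.
    return 1.0 - np.maximum(g, 0.0) ** (1.0 / p)


def _ode_scaled(
    n: float,
    m: float,
    tau: np.ndarray,
    alpha0: float,
    rtol: float,
    atol: float,
    alpha_seed: float,
) -> np.ndarray:
    """Solve d(alpha)/d(tau) = (1-alpha)^n * alpha^m in scaled time."""
    tau_max = float(tau[-1])
    if tau_max == 0.0:
        return np.full_like(tau, alpha0)
    tau_unique, inverse = np.unique(tau, return_inverse=True)

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        a = min(max(y[0], 0.0), 1.0)
        rate = (1.0 - a) ** n
        if m > 0:
            rate *= max(a, alpha_seed) ** m
        return np.array([rate])

    sol = solve_ivp(
        rhs,
        (0.0, tau_max),
        [alpha0],
        method="LSODA",
        t_eval=tau_unique,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed (n={n}, m={m}, alpha0={alpha0}, "
            f"tau_max={tau_max:.3g}): {sol.message}"
        )
    return sol.y[0][inverse]


def integrate_step_isothermal(
    step: ArrheniusStep,
    T: float,
    alpha0: float,
    times_days,
    *,
    method: str = "auto",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    alpha_seed: float = DEFAULT_ALPHA_SEED,
) -> np.ndarray:
    """Integrate one sub-process at constant temperature.

    Parameters
    ----------
    method
        ``"auto"`` uses the closed-form power-law solution when ``m == 0``
        and the adaptive ODE solver otherwise; ``"ode"`` forces the numeric
        path (useful for cross-checks).

    Returns the sub-progress at each requested time (days), clipped to
    [0, 1] and non-decreasing.
    """
    times = np.asarray(times_days, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise KineticsError("times must be a non-empty 1-D array of days")
    if np.any(times < 0):
        raise KineticsError("times must be non-negative")
    if np.any(np.diff(times) < 0):
        raise KineticsError("times must be non-decreasing")
    alpha0 = float(alpha0)
    if not 0.0 <= alpha0 < 1.0:
        raise KineticsError(f"alpha0 must be in [0, 1), got {alpha0}")

    k = rate_constant(step, T)
    tau = k * times * SECONDS_PER_DAY  # dimensionless scaled time

    if method == "auto" and step.m == 0.0:
        alpha = _power_law_closed_form(step.n, tau, alpha0)
    elif method in ("auto", "ode"):
        alpha = _ode_scaled(step.n, step.m, tau, alpha0, rtol, atol, alpha_seed)
    else:
        raise KineticsError(f"unknown integration method {method!r}")

    alpha = np.clip(alpha, 0.0, 1.0)
    return np.maximum.accumulate(alpha)


def integrate_model_isothermal(
    model: KineticModel,
    T: float,
    times_days,
    *,
    state0: ProgressState | None = None,
    **kwargs,
) -> ProgressTrajectory:
    """Integrate every sub-process of ``model`` at one temperature."""
    times = np.asarray(times_days, dtype=float)
    sub0 = state0.sub_alphas if state0 is not None else (0.0,) * model.n_steps
    sub = np.vstack(
        [
            integrate_step_isothermal(step, T, a0, times, **kwargs)
            for step, a0 in zip(model.steps, sub0)
        ]
    )
    return ProgressTrajectory(times_days=times, sub_alphas=sub, weights=model.weights)


def integrate_model_profile(
    model: KineticModel,
    profile: TemperatureProfile,
    grid_days,
    *,
    state0: ProgressState | None = None,
    **kwargs,
) -> ProgressTrajectory:
    """Integrate ``model`` over a piecewise-constant temperature profile.

    ``grid_days`` are output times measured from the start of the profile and
    must lie within its total duration.  Each sub-process is integrated
    independently and is continuous across segment boundaries.
    """
    grid = np.asarray(grid_days, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise KineticsError("grid must be a non-empty 1-D array of days")
    if np.any(np.diff(grid) < 0):
        raise KineticsError("grid times must be non-decreasing")
    if np.any(grid < 0):
        raise KineticsError("grid times must be non-negative")
    total = profile.total_days
    if grid[-1] > total * (1 + 1e-12) + 1e-12:
        raise KineticsError(
            f"grid point {grid[-1]} d lies beyond the profile end ({total} d)"
        )

    n_steps = model.n_steps
    sub = np.empty((n_steps, grid.size))
    current = list(state0.sub_alphas) if state0 is not None else [0.0] * n_steps

    seg_start = 0.0
    idx = 0
    for seg_no, (duration, T) in enumerate(profile.segments):
        seg_end = seg_start + duration
        last = seg_no == len(profile.segments) - 1
        # grid points belonging to this segment (boundary points go to the
        # earlier segment; identical either way by continuity)
        sel = []
        while idx < grid.size and (grid[idx] <= seg_end + 1e-12 or last):
            sel.append(grid[idx])
            idx += 1
        rel = np.array([min(t - seg_start, duration) for t in sel])
        # integrate to requested points and to the segment end to carry state
        times = np.append(rel, duration) if rel.size else np.array([duration])
        times = np.maximum.accumulate(np.clip(times, 0.0, duration))
        for i, (step, a0) in enumerate(zip(model.steps, current)):
            if a0 >= 1.0:
                vals = np.ones_like(times)
            else:
                vals = integrate_step_isothermal(step, T, a0, times, **kwargs)
            if rel.size:
                sub[i, idx - len(sel) : idx] = vals[: len(sel)]
            current[i] = float(vals[-1])
        seg_start = seg_end
    return ProgressTrajectory(times_days=grid, sub_alphas=sub, weights=model.weights)
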