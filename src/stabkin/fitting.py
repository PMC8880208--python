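"""Global nonlinear least-squares fitting of kinetic models to stability data.

A candidate model structure (number of steps, which orders are fixed or free)
plus an attribute map is fitted to all temperatures of one (product,
attribute) dataset at once.  The objective is the unweighted residual sum of
squares between measured and model-predicted attribute values, with
predictions obtained by isothermal integration of the rate law at each
incubation temperature.

Optimization is bounded trust-region least squares (`scipy.optimize.
least_squares`) from multiple starting points: one data-driven start (a
zero-order slope estimate per temperature followed by an Arrhenius line fit)
plus Latin-hypercube samples over the parameter bounds.  The best local
optimum by RSS is returned; ties break on the lexicographically smaller
parameter vector, so results are deterministic for a given seed.

Activation energies are carried in kJ/mol inside the optimizer for
conditioning and reported in J/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .datamodel import AttributeMap, StabilityDataset
from .kinetics import R_GAS, SECONDS_PER_DAY, ArrheniusStep, KineticModel

__all__ = [
    "StepSpec",
    "FitCandidate",
    "FitResult",
    "FitError",
    "objective_rss",
    "fit_candidate",
    "refit_like",
]

# Parameter bounds (box constraints for the optimizer).
LNA_BOUNDS = (-10.0, 60.0)
EA_KJ_BOUNDS = (10.0, 200.0)
N_BOUNDS = (0.0, 10.0)
M_BOUNDS = (0.0, 2.0)
W_BOUNDS = (1e-3, 1.0 - 1e-3)
HMWP_DELTA_BOUNDS = (1e-2, 20.0)
PURITY_DELTA_BOUNDS = (-200.0, -5.0)

DEFAULT_N_STARTS = 24
DEFAULT_SEED = 1255


class FitError(RuntimeError):
    """Fitting failed or the problem is ill-posed."""


@dataclass(frozen=True)
class StepSpec:
    """Structure of one sub-process: fixed value or ``None`` (= free)."""

    n: float | None = 0.0
    m: float | None = 0.0


@dataclass(frozen=True)
class FitCandidate:
    """A model structure to be fitted: 1 or 2 steps with fixed/free orders."""

    label: str
    steps: tuple[StepSpec, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.steps) <= 2:
            raise FitError("candidates have 1 or 2 steps")

    @property
    def n_steps(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class FitResult:
    """A fitted kinetic model with its attribute map and fit metadata."""

    candidate: FitCandidate
    model: KineticModel
    amap: AttributeMap
    rss: float
    n_obs: int
    n_params: int
    converged: bool
    multistart_trace: tuple[float, ...]
    seed: int
    x: tuple[float, ...]  # free-parameter vector at the optimum (internal scale)

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise FitError("rss must be >= 0")
        if self.n_obs <= self.n_params:
            raise FitError("need more observations than free parameters")


# ---------------------------------------------------------------------------
# Parameter vector <-> model decoding


class _ParamCodec:
    """Maps the free-parameter vector to (KineticModel, AttributeMap)."""

    def __init__(self, candidate: FitCandidate, amap: AttributeMap):
        self.candidate = candidate
        self.base_map = amap
        names: list[str] = []
        lo: list[float] = []
        hi: list[float] = []
        for i, spec in enumerate(candidate.steps):
            names.append(f"lnA{i + 1}")
            lo.append(LNA_BOUNDS[0])
            hi.append(LNA_BOUNDS[1])
            names.append(f"Ea{i + 1}_kJ")
            lo.append(EA_KJ_BOUNDS[0])
            hi.append(EA_KJ_BOUNDS[1])
            if spec.n is None:
                names.append(f"n{i + 1}")
                lo.append(N_BOUNDS[0])
                hi.append(N_BOUNDS[1])
            if spec.m is None:
                names.append(f"m{i + 1}")
                lo.append(M_BOUNDS[0])
                hi.append(M_BOUNDS[1])
        if candidate.n_steps == 2:
            names.append("w1")
            lo.append(W_BOUNDS[0])
            hi.append(W_BOUNDS[1])
        if not amap.fix_y0:
            names.append("y0")
            lo.append(-np.inf)  # tightened from data in fit_candidate
            hi.append(np.inf)
        if not amap.fix_delta_max:
            names.append("delta_max")
            b = HMWP_DELTA_BOUNDS if amap.delta_max > 0 else PURITY_DELTA_BOUNDS
            lo.append(b[0])
            hi.append(b[1])
        self.names = names
        self.lower = np.array(lo)
        self.upper = np.array(hi)

    @property
    def n_free(self) -> int:
        return len(self.names)

    def decode(self, x: np.ndarray) -> tuple[KineticModel, AttributeMap]:
        pos = 0
        steps = []
        for spec in self.candidate.steps:
            lnA = x[pos]
            ea = x[pos + 1] * 1e3
            pos += 2
            if spec.n is None:
                n = x[pos]
                pos += 1
            else:
                n = spec.n
            if spec.m is None:
                m = x[pos]
                pos += 1
            else:
                m = spec.m
            steps.append(ArrheniusStep(lnA=lnA, Ea=ea, n=float(n), m=float(m)))
        if self.candidate.n_steps == 2:
            w1 = float(x[pos])
            pos += 1
            weights = (w1, 1.0 - w1)
        else:
            weights = (1.0,)
        y0 = self.base_map.y0
        delta = self.base_map.delta_max
        if not self.base_map.fix_y0:
            y0 = float(x[pos])
            pos += 1
        if not self.base_map.fix_delta_max:
            delta = float(x[pos])
            pos += 1
        model = KineticModel(steps=tuple(steps), weights=weights)
        amap = AttributeMap(
            y0=y0,
            delta_max=delta,
            fix_y0=self.base_map.fix_y0,
            fix_delta_max=self.base_map.fix_delta_max,
        )
        return model, amap

    def encode_model(self, model: KineticModel, amap: AttributeMap) -> np.ndarray:
        """Inverse of :meth:`decode`; used to seed refits from a prior fit."""
        x: list[float] = []
        for spec, step in zip(self.candidate.steps, model.steps):
            x.extend([step.lnA, step.Ea / 1e3])
            if spec.n is None:
                x.append(step.n)
            if spec.m is None:
                x.append(step.m)
        if self.candidate.n_steps == 2:
            x.append(model.weights[0])
        if not self.base_map.fix_y0:
            x.append(amap.y0)
        if not self.base_map.fix_delta_max:
            x.append(amap.delta_max)
        return np.array(x)


# ---------------------------------------------------------------------------
# Objective


def _predict_values(
    model: KineticModel,
    amap: AttributeMap,
    T_rec: np.ndarray,
    t_sec: np.ndarray,
    int_kwargs: dict,
) -> np.ndarray:
    """Vectorized per-record prediction.

    Steps without an autocatalytic term have the closed-form power-law
    solution and are evaluated elementwise over all records at once; steps
    with m > 0 fall back to one ODE solve per temperature group.
    """
    from .kinetics import DEFAULT_ALPHA_SEED, _ode_scaled, _power_law_closed_form

    alpha = np.zeros(T_rec.size)
    for w, step in zip(model.weights, model.steps):
        k = np.exp(step.lnA - step.Ea / (R_GAS * T_rec))
        tau = k * t_sec
        if step.m == 0.0:
            a = _power_law_closed_form(step.n, tau, 0.0)
        else:
            # isothermal progress depends on (n, m) only through the scaled
            # time tau = k*t, so one ODE solve covers every temperature
            order = np.argsort(tau, kind="stable")
            a = np.empty_like(tau)
            a[order] = _ode_scaled(
                step.n,
                step.m,
                tau[order],
                0.0,
                int_kwargs.get("rtol", 1e-8),
                int_kwargs.get("atol", 1e-10),
                int_kwargs.get("alpha_seed", DEFAULT_ALPHA_SEED),
            )
        alpha += w * np.clip(a, 0.0, 1.0)
    return amap.y0 + amap.delta_max * alpha


def _temperature_groups(dataset: StabilityDataset):
    """Pre-sorted (T, times, positions) groups for fast repeated prediction."""
    df = dataset.frame
    groups = []
    for T, grp in df.groupby("temperature_K", sort=True):
        order = np.argsort(grp["time_days"].to_numpy(), kind="stable")
        positions = grp.index.to_numpy()[order]
        times = grp["time_days"].to_numpy()[order]
        groups.append((float(T), times, positions))
    return groups


def predict_dataset_values(
    model: KineticModel,
    amap: AttributeMap,
    dataset: StabilityDataset,
    **int_kwargs,
) -> np.ndarray:
    """Model-predicted attribute value for every record, in record order."""
    T_rec = dataset.frame["temperature_K"].to_numpy()
    t_sec = dataset.frame["time_days"].to_numpy() * SECONDS_PER_DAY
    return _predict_values(model, amap, T_rec, t_sec, int_kwargs)


def objective_rss(
    dataset: StabilityDataset,
    model: KineticModel,
    amap: AttributeMap,
    **int_kwargs,
) -> float:
    """Unweighted residual sum of squares (%^2) over all records."""
    if len(dataset.frame[["product", "attribute"]].drop_duplicates()) > 1:
        raise FitError("objective is defined per (product, attribute); subset first")
    pred = predict_dataset_values(model, amap, dataset, **int_kwargs)
    resid = dataset.frame["value"].to_numpy() - pred
    return float(np.dot(resid, resid))


# ---------------------------------------------------------------------------
# Multi-start fitting


def _smart_start(codec: _ParamCodec, dataset: StabilityDataset) -> np.ndarray:
    """Data-driven start: zero-order slopes per temperature -> Arrhenius line."""
    df = dataset.frame
    amap = codec.base_map
    y0_guess = float(df.loc[df["time_days"] == 0, "value"].mean())
    delta_guess = amap.delta_max
    alpha = (df["value"].to_numpy() - y0_guess) / delta_guess
    alpha = np.clip(alpha, 0.0, 0.999)
    inv_T, ln_k = [], []
    for T, grp_idx in df.groupby("temperature_K").groups.items():
        t = df.loc[grp_idx, "time_days"].to_numpy() * SECONDS_PER_DAY
        a = alpha[df.index.get_indexer(grp_idx)]
        denom = float(np.dot(t, t))
        if denom > 0:
            slope = float(np.dot(t, a)) / denom
            if slope > 0:
                inv_T.append(1.0 / float(T))
                ln_k.append(math.log(slope))
    if len(ln_k) >= 2:
        b, a0 = np.polyfit(inv_T, ln_k, 1)  # ln k = a0 + b / T
        lnA0 = float(np.clip(a0, *LNA_BOUNDS))
        ea_kj0 = float(np.clip(-b * R_GAS / 1e3, *EA_KJ_BOUNDS))
    else:
        lnA0, ea_kj0 = 15.0, 85.0
    x0 = []
    for i, spec in enumerate(codec.candidate.steps):
        # offset the second step so the two branches start distinguishable
        x0.extend([lnA0 - 8.0 * i, max(EA_KJ_BOUNDS[0], ea_kj0 - 35.0 * i)])
        if spec.n is None:
            x0.append(1.0)
        if spec.m is None:
            x0.append(0.1)
    if codec.candidate.n_steps == 2:
        x0.append(0.7)
    if not amap.fix_y0:
        x0.append(y0_guess)
    if not amap.fix_delta_max:
        x0.append(amap.delta_max)
    return np.clip(np.array(x0), codec.lower, codec.upper)


def fit_candidate(
    dataset: StabilityDataset,
    candidate: FitCandidate,
    amap: AttributeMap | None = None,
    *,
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = DEFAULT_SEED,
    x0: np.ndarray | None = None,
    ftol: float = 1e-12,
    xtol: float = 1e-10,
    int_kwargs: dict | None = None,
) -> FitResult:
    """Fit one candidate structure to a single (product, attribute) dataset.

    Parameters
    ----------
    amap
        Attribute map template; its ``fix_*`` flags decide which scale
        parameters are co-estimated.  Defaults to the attribute's standard
        map (`AttributeMap.default_for`).
    n_starts
        Number of optimization starts: one data-driven start plus
        Latin-hypercube samples (deterministic given ``seed``).
    x0
        Optional explicit first start (internal parameter scale); used to
        warm-start bootstrap refits.
    """
    pa = dataset.frame[["product", "attribute"]].drop_duplicates()
    if len(pa) > 1:
        raise FitError("fit one (product, attribute) at a time; use dataset.subset()")
    attribute = str(pa["attribute"].iloc[0])
    if amap is None:
        amap = AttributeMap.default_for(attribute)
    if dataset.frame["temperature_K"].nunique() < 2:
        raise FitError("need >= 2 distinct temperatures for Arrhenius identifiability")

    codec = _ParamCodec(candidate, amap)
    n_free = codec.n_free
    n_obs = len(dataset)
    if n_obs <= n_free:
        raise FitError(f"{n_obs} observations cannot constrain {n_free} free parameters")

    values = dataset.frame["value"].to_numpy()
    if not amap.fix_y0:
        # y0 can only sit near the observed release values
        i = codec.names.index("y0")
        t0 = values[dataset.frame["time_days"].to_numpy() == 0]
        codec.lower[i] = float(t0.min() - 5.0)
        codec.upper[i] = float(t0.max() + 5.0)

    ikw = int_kwargs or {}
    T_rec = dataset.frame["temperature_K"].to_numpy()
    t_sec = dataset.frame["time_days"].to_numpy() * SECONDS_PER_DAY

    def residuals(x: np.ndarray) -> np.ndarray:
        try:
            model, m = codec.decode(x)
            pred = _predict_values(model, m, T_rec, t_sec, ikw)
        except Exception:
            return np.full(n_obs, 1e6)
        return pred - values

    starts: list[np.ndarray] = []
    if x0 is not None:
        starts.append(np.clip(np.asarray(x0, dtype=float), codec.lower, codec.upper))
    else:
        starts.append(_smart_start(codec, dataset))
    n_lhs = max(0, n_starts - 1)
    if n_lhs:
        sampler = qmc.LatinHypercube(d=n_free, seed=seed)
        unit = sampler.random(n_lhs)
        lo = np.where(np.isfinite(codec.lower), codec.lower, -50.0)
        hi = np.where(np.isfinite(codec.upper), codec.upper, 150.0)
        starts.extend(qmc.scale(unit, lo, hi))

    best = None  # (rss, x_tuple, result)
    trace: list[float] = []
    for start in starts:
        try:
            res = least_squares(
                residuals,
                start,
                bounds=(codec.lower, codec.upper),
                method="trf",
                ftol=ftol,
                xtol=xtol,
                gtol=1e-10,
            )
        except Exception:
            trace.append(float("inf"))
            continue
        rss = float(2.0 * res.cost)
        trace.append(rss)
        key = (rss, tuple(res.x))
        if best is None or key < (best[0], best[1]):
            best = (rss, tuple(res.x), res)
    if best is None or not math.isfinite(best[0]):
        raise FitError(
            f"all {len(starts)} starts failed for candidate {candidate.label!r}; "
            f"trace={trace}"
        )

    rss, x_best, res = best
    model, fitted_map = codec.decode(np.asarray(x_best))
    converged = bool(res.status > 0)
    return FitResult(
        candidate=candidate,
        model=model,
        amap=fitted_map,
        rss=rss,
        n_obs=n_obs,
        n_params=n_free,
        converged=converged,
        multistart_trace=tuple(trace),
        seed=seed,
        x=tuple(float(v) for v in x_best),
    )


def prediction_leverages(fit: FitResult, dataset: StabilityDataset) -> np.ndarray:
    """Hat-matrix diagonal h_ii of the fitted regression at the optimum.

    Computed from a forward-difference Jacobian of the per-record predictions
    with respect to the free parameters (Gauss-Newton / linearized leverage).
    Used to rescale residuals for the bootstrap, since fitted residuals have
    variance sigma^2 * (1 - h_ii) and resampling them unadjusted deflates the
    uncertainty band.
    """
    codec = _ParamCodec(fit.candidate, fit.amap)
    x0 = np.asarray(fit.x, dtype=float)

    def pred(x: np.ndarray) -> np.ndarray:
        model, amap = codec.decode(x)
        return predict_dataset_values(model, amap, dataset)

    f0 = pred(x0)
    J = np.empty((len(dataset), x0.size))
    for j in range(x0.size):
        step = 1e-6 * max(1.0, abs(x0[j]))
        xp = x0.copy()
        xp[j] += step
        J[:, j] = (pred(xp) - f0) / step
    # h_ii = row norms of U from the thin SVD of J (rank-robust)
    U, s, _ = np.linalg.svd(J, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    h = np.sum(U[:, :rank] ** 2, axis=1)
    return np.clip(h, 0.0, 0.99)


def refit_like(fit: FitResult, dataset: StabilityDataset, *, n_starts: int = 1) -> FitResult:
    """Refit the same candidate/map structure on new data, warm-started at
    the previous optimum (used by the residual bootstrap)."""
    return fit_candidate(
        dataset,
        fit.candidate,
        fit.amap,
        n_starts=n_starts,
        seed=fit.seed,
        x0=np.asarray(fit.x),
    )
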