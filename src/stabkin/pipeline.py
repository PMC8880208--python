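"""End-to-end analysis pipeline: screen -> fit -> predict -> report.

For every (product, attribute) pair in the input dataset the pipeline screens
the candidate grid, takes the best-ranked fit, predicts the attribute over
the configured storage scenario with a bootstrap prediction band, estimates
shelf life against the specification limits (purity >= 90 % of label claim,
HMWP increase <= 2 %), and, when long-term experimental values are supplied,
tabulates prediction accuracy.  Numeric outputs (CSV/JSON) are the contract;
plots are advisory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    ATTR_HMWP,
    ATTR_PURITY,
    StabilityDataset,
    model_to_dict,
    read_stability_csv,
)
from .kinetics import TemperatureProfile
from .prediction import (
    PredictionScenario,
    bootstrap_prediction_interval,
    shelf_life_estimate,
)
from .selection import default_candidate_grid, screen_and_rank
from .synthetic import STUDY_TEMPERATURES_K

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)

#: Acceptance limits for the drug product: purity within 90-110 % of label
#: claim and at most 2 % HMWP increase.
DEFAULT_SPEC_LIMITS = {ATTR_PURITY: 90.0, ATTR_HMWP: 2.0}


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (loadable from YAML)."""

    data_csv: str
    out_dir: str
    profile: str = "730d@5C,28d@30C"
    products: tuple[str, ...] = ()  # empty = all
    attributes: tuple[str, ...] = ()  # empty = all
    pi_level: float = 99.9
    n_boot: int = 200
    seed: int = 1255
    n_starts: int = 8
    spec_limits: dict = field(default_factory=lambda: dict(DEFAULT_SPEC_LIMITS))
    storage_temperature_C: float = 5.0
    experimental_longterm_csv: str | None = None
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("products", "attributes"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_canonical_json(self) -> str:
        doc = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        return json.dumps(doc, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_json().encode()).hexdigest()[:12]


def _plot_attribute(
    out_path: Path,
    dataset: StabilityDataset,
    fit,
    prediction,
    storage_T_K: float,
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .datamodel import attribute_from_alpha
    from .kinetics import integrate_model_isothermal

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    horizon = np.linspace(0, 913, 200)  # 2.5 years
    for T in STUDY_TEMPERATURES_K:
        traj = integrate_model_isothermal(fit.model, T, horizon)
        ax1.plot(horizon, attribute_from_alpha(fit.amap, traj.overall), label=f"{T - 273.15:.0f} C")
    df = dataset.frame
    ax1.scatter(df["time_days"], df["value"], s=12, c="k", zorder=3)
    ax1.set_xlabel("time (days)")
    ax1.set_ylabel(df["attribute"].iloc[0])
    ax1.legend(fontsize=7)

    ax2.plot(prediction.times_days, prediction.mean, "b-", label="prediction")
    ax2.plot(prediction.times_days, prediction.lower, "b--", lw=0.8)
    ax2.plot(prediction.times_days, prediction.upper, "b--", lw=0.8,
             label=f"{prediction.scenario.pi_level:g}% PI")
    ax2.set_xlabel("time (days)")
    ax2.legend(fontsize=7)
    fig.suptitle(f"{df['product'].iloc[0]} / {df['attribute'].iloc[0]}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the report dict (also written to disk).

    Per-product errors are reported without aborting the batch; raises
    :class:`PipelineError` only when every (product, attribute) fails.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset = read_stability_csv(config.data_csv)
    profile = TemperatureProfile.from_string(config.profile)
    eval_times = np.linspace(0.0, profile.total_days, 74)
    storage_T_K = config.storage_temperature_C + 273.15

    products = list(config.products) or dataset.products
    attributes = list(config.attributes) or dataset.attributes

    experimental = None
    if config.experimental_longterm_csv:
        experimental = pd.read_csv(config.experimental_longterm_csv)

    report: dict = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "profile": config.profile,
        "results": [],
        "errors": [],
    }
    rankings = []
    n_ok = 0
    for product in products:
        for attribute in attributes:
            try:
                sub = dataset.subset(product, attribute)
            except Exception:
                continue
            try:
                ranking = screen_and_rank(
                    sub,
                    default_candidate_grid(),
                    seed=config.seed,
                    n_starts=config.n_starts,
                )
                best = ranking.best
                fit = best.fit
                scenario = PredictionScenario(
                    profile=profile,
                    evaluation_times=tuple(eval_times),
                    pi_level=config.pi_level,
                    n_boot=config.n_boot,
                )
                pred = bootstrap_prediction_interval(sub, fit, scenario, seed=config.seed)
                limit = config.spec_limits.get(attribute)
                shelf = (
                    shelf_life_estimate(fit, storage_T_K, limit)
                    if limit is not None
                    else None
                )
                end_value = float(pred.mean[-1])
                passes = None
                if limit is not None:
                    passes = bool(
                        end_value >= limit
                        if fit.amap.delta_max < 0
                        else end_value <= limit
                    )
                df_rank = ranking.to_frame()
                df_rank.insert(0, "attribute", attribute)
                df_rank.insert(0, "product", product)
                rankings.append(df_rank)

                pred_csv = out_dir / f"prediction_{product}_{attribute}.csv"
                pred.to_frame().to_csv(pred_csv, index=False)
                fit_doc = model_to_dict(fit.model, fit.amap)
                fit_doc["fit"] = {
                    "candidate": fit.candidate.label,
                    "rss": fit.rss,
                    "n_obs": fit.n_obs,
                    "n_params": fit.n_params,
                    "converged": fit.converged,
                    "seed": fit.seed,
                    "config_hash": config.config_hash,
                }
                (out_dir / f"fit_{product}_{attribute}.json").write_text(
                    json.dumps(fit_doc, indent=2)
                )
                if config.make_plots:
                    try:
                        _plot_attribute(
                            out_dir / f"plot_{product}_{attribute}.png",
                            sub, fit, pred, storage_T_K,
                        )
                    except Exception as exc:  # plotting is advisory
                        log.warning("plot failed for %s/%s: %s", product, attribute, exc)

                entry = {
                    "product": product,
                    "attribute": attribute,
                    "best_candidate": best.label,
                    "aic": best.aic,
                    "bic": best.bic,
                    "rss": best.rss,
                    "predicted_end_value": end_value,
                    "pi_lower_end": float(pred.lower[-1]),
                    "pi_upper_end": float(pred.upper[-1]),
                    "spec_limit": limit,
                    "passes_spec": passes,
                    "shelf_life_days": None if shelf is None else shelf.time_days,
                    "shelf_life_status": None if shelf is None else shelf.status,
                }
                if experimental is not None:
                    row = experimental[
                        (experimental["product"] == product)
                        & (experimental["attribute"] == attribute)
                    ]
                    if len(row) == 1:
                        exp_val = float(row["value"].iloc[0])
                        entry["experimental_end_value"] = exp_val
                        entry["delta"] = end_value - exp_val
                report["results"].append(entry)
                n_ok += 1
            except Exception as exc:
                log.error("pipeline failed for %s/%s: %s", product, attribute, exc)
                report["errors"].append(
                    {"product": product, "attribute": attribute, "error": str(exc)}
                )
    if n_ok == 0:
        raise PipelineError("every (product, attribute) analysis failed")
    if rankings:
        pd.concat(rankings, ignore_index=True).to_csv(out_dir / "ranking.csv", index=False)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
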