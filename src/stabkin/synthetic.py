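"""Synthetic accelerated-stability studies with known ground truth.

Emulates the study layout used to calibrate the kinetic models: five
incubation temperatures (5/25/30/37/40 degC), sampling at 0, 13, 33, 46, 60
and 90 days, single-point or duplicate measurements, two quality attributes
per drug product (HPLC purity and SEC HMWP increase), and additive Gaussian
measurement noise.

Twelve named ground-truth models ship as fixtures — the best-fit one- and
two-step rate laws reported for the six formulation/packaging combinations
(purity and HMWP each).  Their attribute-scale constants (purity intercept
98.1 %, purity span -100 points, HMWP plateau 3.2 %) are plausible synthetic
conventions chosen to reproduce the magnitude of the published long-term
values; they are not measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ATTR_HMWP, ATTR_PURITY, AttributeMap, StabilityDataset, attribute_from_alpha
from .kinetics import ArrheniusStep, KineticModel, integrate_model_isothermal

__all__ = [
    "StudyDesign",
    "GroundTruth",
    "simulate_study",
    "printed_model_fixtures",
    "get_fixture",
]

#: 5, 25, 30, 37, 40 degC in Kelvin.
STUDY_TEMPERATURES_K = (278.15, 298.15, 303.15, 310.15, 313.15)
STUDY_TIMEPOINTS_DAYS = (0.0, 13.0, 33.0, 46.0, 60.0, 90.0)

#: Attribute values are physically confined to this window (%).
VALUE_RANGE = (0.0, 110.0)


@dataclass(frozen=True)
class StudyDesign:
    """Accelerated-study layout: temperatures, timepoints, replication, noise."""

    temperatures_K: tuple[float, ...] = STUDY_TEMPERATURES_K
    timepoints_days: tuple[float, ...] = STUDY_TIMEPOINTS_DAYS
    replicates: int = 1
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.temperatures_K) < 2:
            raise ValueError("need >= 2 temperatures for Arrhenius identifiability")
        if 0.0 not in self.timepoints_days:
            raise ValueError("timepoints must include 0 (release value)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """A generating kinetic model plus its attribute map and label."""

    name: str
    attribute: str
    model: KineticModel
    amap: AttributeMap


def simulate_study(design: StudyDesign, truth: GroundTruth) -> StabilityDataset:
    """Simulate one accelerated-stability study.

    For every temperature x timepoint x replicate cell the value is the
    noiseless model attribute plus independent Gaussian noise of SD
    ``design.noise_sd``, clipped to the physically meaningful range
    [0, 110] %.  Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    times = np.asarray(design.timepoints_days, dtype=float)
    rows = []
    for T in design.temperatures_K:
        traj = integrate_model_isothermal(truth.model, T, times)
        clean = attribute_from_alpha(truth.amap, traj.overall)
        for rep in range(1, design.replicates + 1):
            noise = rng.normal(0.0, design.noise_sd, size=times.size) if design.noise_sd > 0 else 0.0
            values = np.clip(clean + noise, *VALUE_RANGE)
            for t, v in zip(times, values):
                rows.append(
                    {
                        "product": truth.name,
                        "attribute": truth.attribute,
                        "temperature_K": T,
                        "time_days": t,
                        "value": v,
                        "replicate": rep,
                    }
                )
    return StabilityDataset(pd.DataFrame(rows))


def _one(lnA, Ea, n=0.0, m=0.0):
    return KineticModel.one_step(lnA, Ea, n, m)


def _two(w1, s1, s2):
    return KineticModel.two_step(w1, ArrheniusStep(*s1), ArrheniusStep(*s2))


# Published best-fit rate laws for the six formulation/packaging combinations.
# Purity loss (one-step models):
_PURITY_MODELS = {
    "Combi_F1-PM1": _one(16.1, 85.8e3, n=4.0, m=0.2),
    "Combi_F2-PM1": _one(15.7, 86.6e3),
    "Combi_F3-PM1": _one(16.7, 89.3e3, n=1.0),
    "Combi_F1-PM2": _one(17.7, 90.0e3, n=4.0, m=0.2),
    "Combi_F2-PM2": _one(16.7, 89.5e3),
    "Combi_F3-PM2": _one(16.1, 85.1e3, n=6.0, m=0.3),
}

# HMWP formation (two one-step and four two-step models);
# step tuples are (lnA, Ea, n, m).
_HMWP_MODELS = {
    "Combi_F1-PM1": _two(0.67, (17.8, 87.5e3, 0.0, 0.0), (4.0, 48.2e3, 0.5, 0.0)),
    "Combi_F2-PM1": _one(13.0, 74.6e3, n=1.0),
    "Combi_F3-PM1": _one(10.1, 66.5e3, n=1.0),
    "Combi_F1-PM2": _two(0.85, (19.4, 95.0e3, 1.0, 0.0), (4.4, 46.4e3, 3.0, 0.0)),
    "Combi_F2-PM2": _two(0.04, (4.3, 46.7e3, 2.0, 0.0), (16.1, 90.2e3, 1.0, 0.0)),
    "Combi_F3-PM2": _two(0.97, (14.3, 85.7e3, 4.0, 0.0), (6.7, 51.2e3, 2.0, 0.0)),
}

#: Synthetic attribute-scale conventions (see module docstring).
PURITY_Y0 = 98.1
PURITY_DELTA_MAX = -100.0
HMWP_DELTA_MAX = 3.2


def printed_model_fixtures() -> list[GroundTruth]:
    """The twelve named ground-truth models (six products x two attributes)."""
    out = []
    for name, model in _PURITY_MODELS.items():
        out.append(
            GroundTruth(
                name=name,
                attribute=ATTR_PURITY,
                model=model,
                amap=AttributeMap.for_purity(y0=PURITY_Y0, delta_max=PURITY_DELTA_MAX),
            )
        )
    for name, model in _HMWP_MODELS.items():
        out.append(
            GroundTruth(
                name=name,
                attribute=ATTR_HMWP,
                model=model,
                amap=AttributeMap.for_hmwp(delta_max=HMWP_DELTA_MAX, fix_delta_max=False),
            )
        )
    return out


def get_fixture(name: str, attribute: str) -> GroundTruth:
    for truth in printed_model_fixtures():
        if truth.name == name and truth.attribute == attribute:
            return truth
    raise KeyError(f"no fixture named {name!r} for attribute {attribute!r}")
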