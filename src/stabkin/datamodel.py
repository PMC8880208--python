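"""Stability measurements, attribute maps, and tidy-CSV I/O.

Measured attributes (purity by HPLC main peak, HMWP increase by SEC) are
linked to the dimensionless reaction progress ``alpha`` by an affine map

    value = y0 + delta_max * alpha

where ``y0`` is the attribute at alpha=0 and ``delta_max`` the signed total
change at alpha=1.  Purity decreases (delta_max < 0); HMWP increase starts at
0 and grows toward a plateau (delta_max > 0) whose magnitude is usually fitted
because the total aggregable fraction is not known a priori.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .kinetics import TEMPERATURE_RANGE_K, ArrheniusStep, KineticModel

__all__ = [
    "ATTR_PURITY",
    "ATTR_HMWP",
    "AttributeMap",
    "StabilityDataset",
    "DesignReport",
    "attribute_from_alpha",
    "alpha_from_attribute",
    "read_stability_csv",
    "write_stability_csv",
    "validate_design",
    "DataError",
]

ATTR_PURITY = "purity"
ATTR_HMWP = "hmwp_increase"

CSV_COLUMNS = ["product", "attribute", "temperature_C", "time_days", "value", "replicate"]


class DataError(ValueError):
    """Malformed stability data or attribute map."""


@dataclass(frozen=True)
class AttributeMap:
    """Affine map between reaction progress and a measured attribute.

    ``fix_y0`` / ``fix_delta_max`` record whether each scale parameter is held
    fixed or estimated alongside the kinetic parameters during fitting.
    """

    y0: float
    delta_max: float
    fix_y0: bool = True
    fix_delta_max: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.y0) and math.isfinite(self.delta_max)):
            raise DataError("y0 and delta_max must be finite")
        if self.delta_max == 0:
            raise DataError("delta_max must be nonzero")

    @classmethod
    def for_purity(cls, y0: float = 98.1, delta_max: float = -100.0, **kw) -> "AttributeMap":
        """Purity-loss scale: alpha=1 corresponds to total loss by default."""
        if delta_max >= 0:
            raise DataError("purity maps require delta_max < 0")
        return cls(y0=y0, delta_max=delta_max, **kw)

    @classmethod
    def for_hmwp(cls, delta_max: float = 3.2, fix_delta_max: bool = False) -> "AttributeMap":
        """HMWP-increase scale: zero at release, fitted plateau by default."""
        if delta_max <= 0:
            raise DataError("HMWP maps require delta_max > 0")
        return cls(y0=0.0, delta_max=delta_max, fix_y0=True, fix_delta_max=fix_delta_max)

    @classmethod
    def identity(cls) -> "AttributeMap":
        """Raw reaction-progress scale (value == alpha)."""
        return cls(y0=0.0, delta_max=1.0)

    @classmethod
    def default_for(cls, attribute: str) -> "AttributeMap":
        if attribute == ATTR_PURITY:
            return cls.for_purity(fix_y0=False)
        if attribute == ATTR_HMWP:
            return cls.for_hmwp()
        return cls.identity()


def attribute_from_alpha(amap: AttributeMap, alpha):
    """Map reaction progress to attribute units (%)."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < 0) or np.any(alpha > 1):
        raise DataError("alpha must be in [0, 1]")
    out = amap.y0 + amap.delta_max * alpha
    return float(out) if out.ndim == 0 else out


def alpha_from_attribute(amap: AttributeMap, value):
    """Exact affine inverse of :func:`attribute_from_alpha`."""
    value = np.asarray(value, dtype=float)
    out = (value - amap.y0) / amap.delta_max
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StabilityDataset:
    """Long-format stability measurements, one row per observation.

    Columns: product (label), attribute (e.g. ``purity`` or
    ``hmwp_increase``), temperature_K, time_days, value (%), replicate (int
    >= 1).  Temperatures are Kelvin in memory, Celsius in CSV files.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.reset_index(drop=True).copy()
        required = {"product", "attribute", "temperature_K", "time_days", "value", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"dataset missing columns: {sorted(missing)}")
        for col in ("temperature_K", "time_days", "value"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        df["replicate"] = df["replicate"].astype(int)
        if df.empty:
            raise DataError("dataset is empty")
        if (df["time_days"] < 0).any():
            raise DataError("times must be >= 0")
        if not np.isfinite(df["value"]).all():
            raise DataError("values must be finite")
        if (df["replicate"] < 1).any():
            raise DataError("replicate indices start at 1")
        lo, hi = TEMPERATURE_RANGE_K
        bad_T = df[(df["temperature_K"] < lo) | (df["temperature_K"] > hi)]
        if not bad_T.empty:
            raise DataError(
                f"temperatures outside [{lo}, {hi}] K in rows {bad_T.index.tolist()}"
            )
        keys = df[["product", "attribute", "temperature_K", "time_days", "replicate"]]
        dup = keys.duplicated()
        if dup.any():
            raise DataError(f"duplicate measurement keys in rows {df.index[dup].tolist()}")
        for (prod, attr), grp in df.groupby(["product", "attribute"], sort=False):
            if not (grp["time_days"] == 0).any():
                raise DataError(f"no time-0 record for product={prod!r}, attribute={attr!r}")
        object.__setattr__(self, "frame", df)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def products(self) -> list[str]:
        return list(dict.fromkeys(self.frame["product"]))

    @property
    def attributes(self) -> list[str]:
        return list(dict.fromkeys(self.frame["attribute"]))

    @property
    def temperatures_K(self) -> np.ndarray:
        return np.sort(self.frame["temperature_K"].unique())

    def subset(self, product: str, attribute: str) -> "StabilityDataset":
        df = self.frame[
            (self.frame["product"] == product) & (self.frame["attribute"] == attribute)
        ]
        if df.empty:
            raise DataError(f"no records for product={product!r}, attribute={attribute!r}")
        return StabilityDataset(df)

    def with_values(self, values: np.ndarray) -> "StabilityDataset":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self),):
            raise DataError("replacement values must match record count")
        df = self.frame.copy()
        df["value"] = values
        return StabilityDataset(df)


def read_stability_csv(path) -> StabilityDataset:
    """Read a tidy stability CSV (header ``product,attribute,temperature_C,
    time_days,value,replicate``); temperatures converted degC -> K."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path.name}: missing columns {sorted(missing)}")
    for col in ("temperature_C", "time_days", "value"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index.tolist()
            raise DataError(f"{path.name}: non-numeric {col!r} in rows {bad}") from exc
    neg = df[df["time_days"] < 0].index.tolist()
    if neg:
        raise DataError(f"{path.name}: negative time_days in rows {neg}")
    df["temperature_K"] = df["temperature_C"] + 273.15
    return StabilityDataset(df[["product", "attribute", "temperature_K", "time_days", "value", "replicate"]])


def write_stability_csv(dataset: StabilityDataset, path) -> None:
    df = dataset.frame.copy()
    df["temperature_C"] = (df["temperature_K"] - 273.15).round(10)
    df[CSV_COLUMNS].to_csv(path, index=False)


@dataclass(frozen=True)
class DesignReport:
    """Summary of a study design against good-modeling-practice guidance
    (>= 20 points, >= 3 temperatures, replicates recommended)."""

    n_points: int
    n_temperatures: int
    temperatures_K: tuple[float, ...]
    n_timepoints: int
    has_replicates: bool
    warnings: tuple[str, ...] = ()


def validate_design(dataset: StabilityDataset) -> DesignReport:
    """Check a dataset against recommended study-design minimums."""
    df = dataset.frame
    temps = tuple(np.sort(df["temperature_K"].unique()))
    warnings: list[str] = []
    n = len(df)
    has_reps = (df["replicate"] > 1).any()
    if n < 20:
        warnings.append(f"only {n} points; >= 20 recommended")
    if len(temps) < 3:
        warnings.append(f"only {len(temps)} temperatures; >= 3 recommended")
    if not has_reps:
        warnings.append("no replicates; duplicates recommended for outlier detection")
    return DesignReport(
        n_points=n,
        n_temperatures=len(temps),
        temperatures_K=temps,
        n_timepoints=df["time_days"].nunique(),
        has_replicates=bool(has_reps),
        warnings=tuple(warnings),
    )


# ---------------------------------------------------------------------------
# Versioned JSON serialization of fitted models


def model_to_dict(model: KineticModel, amap: AttributeMap) -> dict:
    return {
        "format": "stabkin-fit",
        "version": 1,
        "model": {
            "steps": [
                {"lnA": s.lnA, "Ea": s.Ea, "n": s.n, "m": s.m} for s in model.steps
            ],
            "weights": list(model.weights),
        },
        "map": {
            "y0": amap.y0,
            "delta_max": amap.delta_max,
            "fix_y0": amap.fix_y0,
            "fix_delta_max": amap.fix_delta_max,
        },
    }


def model_from_dict(doc: dict) -> tuple[KineticModel, AttributeMap]:
    if doc.get("format") != "stabkin-fit":
        raise DataError("not a stabkin fit document")
    steps = tuple(ArrheniusStep(**s) for s in doc["model"]["steps"])
    model = KineticModel(steps=steps, weights=tuple(doc["model"]["weights"]))
    amap = AttributeMap(**doc["map"])
    return model, amap


def save_model_json(model: KineticModel, amap: AttributeMap, path, extra: dict | None = None) -> None:
    doc = model_to_dict(model, amap)
    if extra:
        doc["fit"] = extra
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model_json(path) -> tuple[KineticModel, AttributeMap]:
    return model_from_dict(json.loads(Path(path).read_text()))
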