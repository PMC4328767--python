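"""Domain types, delimited-text I/O, and trait preparation.

The analyses in this package operate on long-format repeated-measures
tables: one row per individual x trial, with columns for behavioral
scores from an open-field trial, a binary emergence outcome after a
simulated predator strike, and waterborne steroid release rates
collected before and after each trial.

Traits are prepared for mixed-model analysis in two steps that mirror
standard practice in animal-personality research:

1. a variance-stabilizing transform (square root for behavioral counts
   and durations, natural log for hormone release rates), and
2. rescaling to standard-deviation units, i.e. division by the pooled
   sample SD of the transformed trait.  The mean is deliberately *not*
   removed: the model's mean fixed effect absorbs it, and on this scale
   the among-individual variance of a trait is directly interpretable
   as its repeatability.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BEHAVIOR_TRAITS",
    "HORMONE_TRAITS",
    "EMERGENCE_TRAIT",
    "COLUMNS",
    "DataError",
    "ObservationTable",
    "TraitSpec",
    "compute_release_rate",
    "mass_adjust_ln",
    "prepare_trait",
    "read_observations",
    "standardize_series",
    "transform_series",
    "write_observations",
]

#: Canonical column order for observation tables.
COLUMNS = [
    "individual_id",
    "trial_number",
    "day_order",
    "stack",
    "mass",
    "TL",
    "ACT",
    "AC",
    "TIM",
    "TOR",
    "emREF",
    "F_PRE",
    "F_POST",
    "KT11_PRE",
    "KT11_POST",
]

BEHAVIOR_NAMES = ["TL", "ACT", "AC", "TIM", "TOR"]
HORMONE_NAMES = ["F_PRE", "F_POST", "KT11_PRE", "KT11_POST"]
PERCENT_NAMES = {"ACT", "AC"}


class DataError(ValueError):
    """Raised when an observation table violates its invariants."""


@dataclass(frozen=True)
class TraitSpec:
    """How a single trait enters the mixed model.

    Parameters
    ----------
    name:
        Column name in the observation table.
    transform:
        ``"none"``, ``"sqrt"`` or ``"ln"``; applied before scaling.
    scale_to_sd:
        Divide the transformed values by their pooled sample SD so the
        trait is in standard-deviation units.
    fixed_effects:
        Ordered subset of ``{"mean", "trial_number", "stack",
        "day_order", "mass"}``.
    """

    name: str
    transform: str = "none"
    scale_to_sd: bool = True
    fixed_effects: tuple = ("mean", "trial_number", "stack", "day_order")

    def __post_init__(self):
        if self.transform not in ("none", "sqrt", "ln"):
            raise ValueError(f"unknown transform {self.transform!r}")
        allowed = {"mean", "trial_number", "stack", "day_order", "mass"}
        bad = set(self.fixed_effects) - allowed
        if bad:
            raise ValueError(f"unknown fixed effects {sorted(bad)}")


def behavior_spec(name: str) -> TraitSpec:
    return TraitSpec(name=name, transform="sqrt", scale_to_sd=True,
                     fixed_effects=("mean", "trial_number", "stack", "day_order"))


def hormone_spec(name: str) -> TraitSpec:
    # Mass is a covariate for hormones only: release into holding water
    # scales with gill area, hence with body size.
    return TraitSpec(name=name, transform="ln", scale_to_sd=True,
                     fixed_effects=("mean", "trial_number", "stack", "day_order", "mass"))


BEHAVIOR_TRAITS = tuple(behavior_spec(n) for n in BEHAVIOR_NAMES)
HORMONE_TRAITS = tuple(hormone_spec(n) for n in HORMONE_NAMES)
EMERGENCE_TRAIT = TraitSpec(
    name="emREF", transform="none", scale_to_sd=False,
    fixed_effects=("mean", "trial_number", "stack", "day_order"),
)


@dataclass
class ObservationTable:
    """Long-format repeated-measures table, one row per individual x trial."""

    data: pd.DataFrame

    def __post_init__(self):
        self.data = self.data.reset_index(drop=True)
        validate_observations(self.data)

    @property
    def individuals(self) -> list:
        return sorted(self.data["individual_id"].unique().tolist())

    @property
    def trials(self) -> list:
        return sorted(self.data["trial_number"].unique().tolist())

    def __len__(self) -> int:
        return len(self.data)


def validate_observations(df: pd.DataFrame) -> None:
    for col in ("individual_id", "trial_number"):
        if col not in df.columns:
            raise DataError(f"missing required column {col!r}")
    dup = df.duplicated(subset=["individual_id", "trial_number"])
    if dup.any():
        keys = df.loc[dup, ["individual_id", "trial_number"]].values.tolist()
        raise DataError(f"duplicate (individual, trial) keys: {keys[:5]}")
    tn = pd.to_numeric(df["trial_number"], errors="raise")
    if (tn < 1).any():
        raise DataError("trial_number must be >= 1")
    if "mass" in df.columns:
        m = df["mass"].dropna()
        if (m <= 0).any():
            raise DataError("mass must be positive where present")
    if "emREF" in df.columns:
        e = df["emREF"].dropna()
        if not e.isin([0, 1]).all():
            raise DataError("emREF must be binary 0/1")
    for col in PERCENT_NAMES & set(df.columns):
        v = df[col].dropna()
        if ((v < 0) | (v > 100)).any():
            raise DataError(f"{col} must lie in [0, 100]")


# ---------------------------------------------------------------------------
# Trait preparation


def transform_series(values, transform: str):
    """Apply a variance-stabilizing transform element-wise.

    Missing values propagate.  ``sqrt`` requires non-negative input and
    ``ln`` strictly positive input; violations raise :class:`DataError`
    naming the offending positions.
    """
    arr = pd.Series(values, dtype=float)
    if transform == "none":
        return arr
    if transform == "sqrt":
        bad = arr.index[(arr < 0).fillna(False)]
        if len(bad):
            raise DataError(f"sqrt transform: negative values at rows {list(bad[:5])}")
        return np.sqrt(arr)
    if transform == "ln":
        bad = arr.index[(arr <= 0).fillna(False)]
        if len(bad):
            raise DataError(f"ln transform: non-positive values at rows {list(bad[:5])}")
        return np.log(arr)
    raise ValueError(f"unknown transform {transform!r}")


def standardize_series(values):
    """Divide by the pooled sample SD (``n - 1`` denominator).

    The SD is computed across *all* non-missing observations of the
    trait, pooled over individuals and trials.  The mean is left in
    place; the model's mean fixed effect absorbs it.  The result has
    sample SD exactly 1.
    """
    arr = pd.Series(values, dtype=float)
    ok = arr.dropna()
    if len(ok) < 2:
        raise DataError("standardization needs >= 2 non-missing values")
    sd = ok.std(ddof=1)
    if not np.isfinite(sd) or sd <= 0:
        raise DataError("standardization: zero spread (constant trait)")
    return arr / sd


def prepare_trait(df: pd.DataFrame, spec: TraitSpec) -> pd.Series:
    """Transformed (and optionally SD-scaled) copy of one trait column."""
    if spec.name not in df.columns:
        raise DataError(f"trait column {spec.name!r} not in table")
    out = transform_series(df[spec.name], spec.transform)
    if spec.scale_to_sd:
        out = standardize_series(out)
    return out


# ---------------------------------------------------------------------------
# Hormone helpers


def compute_release_rate(total_mass_pg, collection_minutes):
    """Scale an assayed steroid total (pg) to a per-hour release rate (pg/h)."""
    total = np.asarray(total_mass_pg, dtype=float)
    minutes = np.asarray(collection_minutes, dtype=float)
    if np.any(minutes <= 0):
        raise DataError("collection duration must be positive")
    if np.any(total < 0):
        raise DataError("steroid total must be non-negative")
    out = total * (60.0 / minutes)
    return float(out) if out.ndim == 0 else out


def mass_adjust_ln(rate, mass):
    """Natural log of a mass-scaled release rate, ln(pg/h/g).

    Used only in the waterborne-vs-whole-body validation analysis; the
    repeated-measures models control for mass as a fixed effect instead.
    """
    r = np.asarray(rate, dtype=float)
    m = np.asarray(mass, dtype=float)
    if np.any(r <= 0) or np.any(m <= 0):
        raise DataError("mass_adjust_ln requires positive rate and mass")
    out = np.log(r / m)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# I/O


def read_observations(path, sep: str = ",", na_values: str = "NA",
                      strict: bool = False) -> ObservationTable:
    """Read a delimited observation file (header row required).

    Under ``strict=True`` any column outside the canonical schema is an
    error; otherwise extra columns are carried through untouched.
    """
    df = pd.read_csv(path, sep=sep, na_values=[na_values], keep_default_na=True)
    if strict:
        unknown = [c for c in df.columns if c not in COLUMNS]
        if unknown:
            raise DataError(f"unknown columns {unknown} (strict mode)")
    return ObservationTable(df)


def write_observations(table: ObservationTable, path, sep: str = ",",
                       na_rep: str = "NA") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, sep=sep, index=False, na_rep=na_rep)
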