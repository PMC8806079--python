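"""Cohort data model, CSV round-trip I/O and validation.

The cohort table is a plain UTF-8 CSV with a fixed lower-snake-case header::

    age,sex,race,physical_activity,alcohol_use,current_smoker,
    cotinine,crp,bmi,ltl_bp,ts_ratio

Conventions
-----------
* Decimal separator is ``.``; floats are written with ``repr`` so that a
  write -> read round-trip is bit exact.
* Missing values are empty cells.
* Below-LOD biomarker values are encoded as ``"<VALUE"`` strings (e.g.
  ``"<0.05"``), mirroring laboratory exports.  In memory they are split into
  a numeric column holding the LOD threshold and a boolean ``*_below_lod``
  flag.
* ``current_smoker`` is written as ``true`` / ``false``.

Exactly one of ``ltl_bp`` / ``ts_ratio`` is required per record (both may be
present); conversion between the two lives in :mod:`thirdvar.preprocess`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CohortFormatError,
    CohortParseError,
    ContractError,
    EmptyInputError,
)

SEX_LEVELS = ("male", "female")
RACE_LEVELS = ("white", "black")
ACTIVITY_LEVELS = ("none", "moderate", "vigorous")
ALCOHOL_LEVELS = ("never", "<=1 day/week", "2-3 days/week", "4-7 days/week")

#: Columns of the external CSV dialect, in order.
CSV_COLUMNS = (
    "age",
    "sex",
    "race",
    "physical_activity",
    "alcohol_use",
    "current_smoker",
    "cotinine",
    "crp",
    "bmi",
    "ltl_bp",
    "ts_ratio",
)

#: Columns that must be present in the header.  Of the two telomere columns
#: at least one is required.
MANDATORY_COLUMNS = CSV_COLUMNS[:9]

#: Biomarkers that may carry a "<LOD" encoding.
LOD_COLUMNS = ("cotinine", "crp")

#: Variable names accepted by :class:`ModelSpec`.  ``ltl`` resolves to
#: ``ltl_bp`` (converted from ``ts_ratio`` when needed).
MODEL_VARIABLES = (
    "age",
    "sex",
    "race",
    "physical_activity",
    "alcohol_use",
    "current_smoker",
    "cotinine",
    "crp",
    "bmi",
    "ltl",
)

#: Internal (in-memory) frame columns.
_FRAME_COLUMNS = (
    "age",
    "sex",
    "race",
    "physical_activity",
    "alcohol_use",
    "current_smoker",
    "cotinine",
    "cotinine_below_lod",
    "crp",
    "crp_below_lod",
    "bmi",
    "ltl_bp",
    "ts_ratio",
)

_CATEGORY_LEVELS: Mapping[str, tuple] = {
    "sex": SEX_LEVELS,
    "race": RACE_LEVELS,
    "physical_activity": ACTIVITY_LEVELS,
    "alcohol_use": ALCOHOL_LEVELS,
}

_RANGES = {
    # field -> (low, high, low_inclusive, high_inclusive)
    "age": (18.0, 120.0, True, True),
    "bmi": (10.0, 80.0, False, False),
    "cotinine": (0.0, math.inf, False, False),
    "crp": (0.0, math.inf, False, False),
    "ltl_bp": (0.0, math.inf, False, False),
    "ts_ratio": (0.0, math.inf, False, False),
}


@dataclass
class CohortTable:
    """A validated participant table plus provenance metadata.

    ``frame`` uses the internal column layout (`_FRAME_COLUMNS`), with
    below-LOD biomarkers split into a numeric threshold and a boolean flag.
    """

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.frame) == 0:
            raise EmptyInputError("cohort table has no rows")
        missing = [c for c in _FRAME_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ContractError(f"cohort frame missing columns: {missing}")
        self.frame = self.frame.loc[:, list(_FRAME_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n(self) -> int:
        return len(self.frame)

    def copy(self) -> "CohortTable":
        return CohortTable(self.frame.copy(), self.provenance)


@dataclass(frozen=True)
class ModelSpec:
    """Declaration of one third-variable analysis.

    ``predictor`` (X), ``outcome`` (Y), up to two ``third_variables`` (Z),
    adjustment ``covariates`` and per-variable transforms (``log`` or
    ``identity``).
    """

    predictor: str = "cotinine"
    outcome: str = "ltl"
    third_variables: tuple[str, ...] = ("bmi", "crp")
    covariates: tuple[str, ...] = (
        "age",
        "race",
        "sex",
        "physical_activity",
        "alcohol_use",
    )
    transforms: Mapping[str, str] = field(
        default_factory=lambda: {"cotinine": "log", "crp": "log"}
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "third_variables", tuple(self.third_variables))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "transforms", dict(self.transforms))
        names = (
            [self.predictor, self.outcome]
            + list(self.third_variables)
            + list(self.covariates)
        )
        for name in names:
            if name not in MODEL_VARIABLES:
                raise ContractError(
                    f"unknown model variable {name!r}; expected one of {MODEL_VARIABLES}"
                )
        if len(set(names)) != len(names):
            raise ContractError(f"model variables must be mutually distinct: {names}")
        if len(self.third_variables) > 2:
            raise ContractError("at most two third variables are supported")
        for var, tr in self.transforms.items():
            if tr not in ("log", "identity"):
                raise ContractError(f"unknown transform {tr!r} for {var!r}")

    @property
    def variables(self) -> tuple[str, ...]:
        """All variables entering the analysis, predictor first."""
        return (
            (self.predictor,)
            + self.third_variables
            + (self.outcome,)
            + self.covariates
        )

    def transform_of(self, var: str) -> str:
        return dict(self.transforms).get(var, "identity")

    def replace(self, **kwargs) -> "ModelSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass
class FieldReport:
    missing: int = 0
    invalid: int = 0


@dataclass
class ValidationReport:
    """Per-field missingness and range/category violation counts."""

    n_records: int
    fields: dict[str, FieldReport]
    #: records with neither ltl_bp nor ts_ratio
    missing_ltl: int = 0

    @property
    def total_violations(self) -> int:
        return self.missing_ltl + sum(f.invalid for f in self.fields.values())

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "missing_ltl": self.missing_ltl,
            "total_violations": self.total_violations,
            "fields": {
                k: {"missing": v.missing, "invalid": v.invalid}
                for k, v in self.fields.items()
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _parse_float(raw: str) -> float:
    raw = raw.strip()
    if raw == "":
        return math.nan
    return float(raw)


def _parse_lod(raw: str) -> tuple[float, bool]:
    """Parse a biomarker cell: plain float, ``"<x"`` string, or missing."""
    raw = raw.strip()
    if raw == "":
        return math.nan, False
    if raw.startswith("<"):
        return float(raw[1:]), True
    return float(raw), False


def _parse_bool(raw: str):
    raw = raw.strip().lower()
    if raw == "":
        return math.nan
    if raw in ("true", "1", "yes"):
        return True
    if raw in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {raw!r}")


def read_cohort(path: str | Path, provenance: str | None = None) -> CohortTable:
    """Read a cohort CSV into a validated :class:`CohortTable`.

    Raises :class:`CohortFormatError` when a mandatory column is absent,
    :class:`EmptyInputError` for a row-less file and :class:`CohortParseError`
    (listing every offending cell) when type coercion fails.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path} is empty") from exc
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    if "ltl_bp" not in raw.columns and "ts_ratio" not in raw.columns:
        raise CohortFormatError("need at least one of columns: ltl_bp, ts_ratio")
    if len(raw) == 0:
        raise EmptyInputError(f"{path} contains a header but no rows")

    issues: list[tuple[int, str, str]] = []
    data: dict[str, list] = {c: [] for c in _FRAME_COLUMNS}

    for i, row in enumerate(raw.itertuples(index=False)):
        rec = dict(zip(raw.columns, row))
        for col in ("age", "bmi", "ltl_bp", "ts_ratio"):
            cell = rec.get(col, "")
            try:
                data[col].append(_parse_float(cell))
            except ValueError:
                issues.append((i, col, cell))
                data[col].append(math.nan)
        for col in LOD_COLUMNS:
            cell = rec.get(col, "")
            try:
                value, below = _parse_lod(cell)
            except ValueError:
                issues.append((i, col, cell))
                value, below = math.nan, False
            data[col].append(value)
            data[f"{col}_below_lod"].append(below)
        try:
            data["current_smoker"].append(_parse_bool(rec.get("current_smoker", "")))
        except ValueError:
            issues.append((i, "current_smoker", rec.get("current_smoker", "")))
            data["current_smoker"].append(math.nan)
        for col in _CATEGORY_LEVELS:
            cell = rec.get(col, "").strip()
            data[col].append(cell if cell != "" else math.nan)

    if issues:
        raise CohortParseError(issues)

    frame = pd.DataFrame(data)
    for col in ("age", "cotinine", "crp", "bmi", "ltl_bp", "ts_ratio"):
        frame[col] = frame[col].astype(float)
    return CohortTable(frame, provenance or str(path))


def _format_float(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return repr(float(x))


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort back to the CSV dialect (exact float round-trip)."""
    frame = cohort.frame
    out = pd.DataFrame(index=frame.index)
    for col in ("age", "bmi", "ltl_bp", "ts_ratio"):
        out[col] = frame[col].map(_format_float)
    for col in LOD_COLUMNS:
        below = frame[f"{col}_below_lod"].to_numpy()
        vals = frame[col].map(_format_float).to_numpy(dtype=object)
        out[col] = np.where(below, np.char.add("<", vals.astype(str)), vals)
    out["current_smoker"] = frame["current_smoker"].map(
        lambda v: "" if (v is None or (isinstance(v, float) and math.isnan(v)))
        else ("true" if v else "false")
    )
    for col in _CATEGORY_LEVELS:
        out[col] = frame[col].map(lambda v: "" if (isinstance(v, float) and math.isnan(v)) else v)
    out = out.loc[:, list(CSV_COLUMNS)]
    out.to_csv(path, index=False)


def _is_missing(series: pd.Series) -> pd.Series:
    return series.isna()


def validate_cohort(cohort: CohortTable) -> ValidationReport:
    """Count per-field missing values and range/category violations.

    Purely a reporting operation: never mutates or drops data.
    """
    frame = cohort.frame
    fields: dict[str, FieldReport] = {}

    for col, (lo, hi, lo_inc, hi_inc) in _RANGES.items():
        series = frame[col]
        missing = int(series.isna().sum())
        vals = series.dropna()
        ok_lo = vals >= lo if lo_inc else vals > lo
        ok_hi = vals <= hi if hi_inc else vals < hi
        invalid = int((~(ok_lo & ok_hi)).sum())
        fields[col] = FieldReport(missing=missing, invalid=invalid)

    for col, levels in _CATEGORY_LEVELS.items():
        series = frame[col]
        missing = int(series.isna().sum())
        vals = series.dropna()
        invalid = int((~vals.isin(levels)).sum())
        fields[col] = FieldReport(missing=missing, invalid=invalid)

    smoker = frame["current_smoker"]
    fields["current_smoker"] = FieldReport(
        missing=int(smoker.isna().sum()),
        invalid=int(sum(1 for v in smoker.dropna() if not isinstance(v, (bool, np.bool_)))),
    )

    missing_ltl = int((frame["ltl_bp"].isna() & frame["ts_ratio"].isna()).sum())
    # a below-LOD flag never counts as missing, but the threshold must be valid
    return ValidationReport(n_records=len(frame), fields=fields, missing_ltl=missing_ltl)


def cohort_from_records(records: Sequence[Mapping], provenance: str = "") -> CohortTable:
    """Build a CohortTable from plain dicts (tests and generators)."""
    frame = pd.DataFrame(list(records))
    for col in _FRAME_COLUMNS:
        if col not in frame.columns:
            if col.endswith("_below_lod"):
                frame[col] = False
            else:
                frame[col] = math.nan
    return CohortTable(frame, provenance)
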