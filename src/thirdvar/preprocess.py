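"""Raw cohort -> numeric design: transforms, coding, filtering, scaling.

The design matrix carries the per-column mean/SD recorded at construction so
standardized coefficients can be computed from a raw least-squares fit
without refitting on z-scored data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    ACTIVITY_LEVELS,
    ALCOHOL_LEVELS,
    RACE_LEVELS,
    SEX_LEVELS,
    CohortTable,
    ModelSpec,
)
from .errors import (
    CodingError,
    ContractError,
    DegenerateScaleError,
    DomainError,
    EmptyAnalysisError,
)

#: Affine T/S ratio -> base pairs conversion constants.
TS_INTERCEPT = 3274.0
TS_SLOPE = 2413.0

LodPolicy = Literal["strict", "lod_over_sqrt2", "half_lod"]

#: Design-column name for each model variable.
DESIGN_NAMES = {
    "age": "age",
    "sex": "female_sex",
    "race": "black_race",
    "physical_activity": "active_pa",
    "alcohol_use": "alcohol_use",
    "current_smoker": "current_smoker",
    "bmi": "bmi",
    "ltl": "ltl_bp",
}


def ts_to_bp(ts_ratio):
    """Convert telomere T/S ratio(s) to absolute length in base pairs.

    ``bp = 3274 + 2413 * ts``.  Raises :class:`DomainError` for a
    non-positive ratio (the intercept itself is exposed via ``ts_to_bp(0)``
    only through the module constants).
    """
    arr = np.asarray(ts_ratio, dtype=float)
    if np.any(arr < 0):
        raise DomainError("T/S ratio must be positive")
    out = TS_INTERCEPT + TS_SLOPE * arr
    return float(out) if np.isscalar(ts_ratio) or arr.ndim == 0 else out


def bp_to_ts(ltl_bp):
    """Inverse of :func:`ts_to_bp`."""
    arr = np.asarray(ltl_bp, dtype=float)
    out = (arr - TS_INTERCEPT) / TS_SLOPE
    return float(out) if np.isscalar(ltl_bp) or arr.ndim == 0 else out


def lod_substitute(lod_value: float, policy: LodPolicy) -> float:
    """Numeric stand-in for a value reported only as below ``lod_value``."""
    if policy == "lod_over_sqrt2":
        return lod_value / math.sqrt(2.0)
    if policy == "half_lod":
        return lod_value / 2.0
    if policy == "strict":
        raise DomainError("below-LOD value encountered with policy 'strict'")
    raise ContractError(f"unknown LOD policy {policy!r}")


def log_transform(
    values,
    below_lod=None,
    policy: LodPolicy = "lod_over_sqrt2",
) -> tuple[np.ndarray, int]:
    """Natural log with below-LOD substitution.

    Returns the transformed array and the number of substitutions applied.
    With policy ``strict`` any below-LOD or non-positive entry raises
    :class:`DomainError`.
    """
    vals = np.asarray(values, dtype=float).copy()
    n_sub = 0
    if below_lod is not None:
        mask = np.asarray(below_lod, dtype=bool)
        if mask.any():
            if policy == "strict":
                raise DomainError(f"{int(mask.sum())} below-LOD value(s) with policy 'strict'")
            vals[mask] = [lod_substitute(v, policy) for v in vals[mask]]
            n_sub = int(mask.sum())
    finite = ~np.isnan(vals)
    if np.any(vals[finite] <= 0):
        raise DomainError("log transform requires strictly positive values")
    with np.errstate(invalid="ignore"):
        return np.log(vals), n_sub


def encode_record(sex: str, race: str, physical_activity: str, alcohol_use: str,
                  current_smoker: bool) -> tuple[int, int, int, int, int]:
    """Covariate coding for a single record.

    Returns ``(black_race, female_sex, active_pa, alcohol_score, smoker)``.
    """
    for value, levels, name in (
        (sex, SEX_LEVELS, "sex"),
        (race, RACE_LEVELS, "race"),
        (physical_activity, ACTIVITY_LEVELS, "physical_activity"),
        (alcohol_use, ALCOHOL_LEVELS, "alcohol_use"),
    ):
        if value not in levels:
            raise CodingError(f"unknown {name} category {value!r}")
    return (
        int(race == "black"),
        int(sex == "female"),
        int(physical_activity in ("moderate", "vigorous")),
        ALCOHOL_LEVELS.index(alcohol_use),
        int(bool(current_smoker)),
    )


def _encode_category(series: pd.Series, levels, name: str) -> None:
    bad = series.dropna()[~series.dropna().isin(levels)]
    if len(bad):
        raise CodingError(f"unknown {name} category {bad.iloc[0]!r}")


def encode_covariates(cohort: CohortTable) -> dict[str, np.ndarray]:
    """Vectorized covariate coding for a whole cohort.

    race -> black=1; sex -> female=1; physical activity -> any activity=1;
    alcohol -> ordinal 0-3 in category order; current_smoker -> 0/1.
    Missing values propagate as NaN.
    """
    frame = cohort.frame
    for col, levels in (
        ("sex", SEX_LEVELS),
        ("race", RACE_LEVELS),
        ("physical_activity", ACTIVITY_LEVELS),
        ("alcohol_use", ALCOHOL_LEVELS),
    ):
        _encode_category(frame[col], levels, col)

    def ind(series, predicate):
        out = np.full(len(series), np.nan)
        notna = series.notna().to_numpy()
        out[notna] = [float(predicate(v)) for v in series[notna]]
        return out

    return {
        "black_race": ind(frame["race"], lambda v: v == "black"),
        "female_sex": ind(frame["sex"], lambda v: v == "female"),
        "active_pa": ind(frame["physical_activity"], lambda v: v in ("moderate", "vigorous")),
        "alcohol_use": ind(frame["alcohol_use"], ALCOHOL_LEVELS.index),
        "current_smoker": ind(frame["current_smoker"], bool),
    }


def _variable_missing_mask(cohort: CohortTable, var: str) -> np.ndarray:
    """True where ``var`` is unavailable for analysis in a given row."""
    frame = cohort.frame
    if var == "ltl":
        return (frame["ltl_bp"].isna() & frame["ts_ratio"].isna()).to_numpy()
    col = {"cotinine": "cotinine", "crp": "crp", "bmi": "bmi"}.get(var, var)
    return frame[col].isna().to_numpy()


def complete_case_filter(cohort: CohortTable, spec: ModelSpec) -> tuple[CohortTable, int]:
    """Retain rows with non-missing values for every variable in ``spec``.

    Below-LOD biomarker entries count as present (substitution happens at
    transform time).  Raises :class:`EmptyAnalysisError` when nothing
    survives.
    """
    drop = np.zeros(len(cohort), dtype=bool)
    for var in spec.variables:
        drop |= _variable_missing_mask(cohort, var)
    kept = cohort.frame.loc[~drop]
    n_removed = int(drop.sum())
    if len(kept) == 0:
        raise EmptyAnalysisError("no complete cases for the requested model")
    return CohortTable(kept.copy(), cohort.provenance), n_removed


def standardize(column) -> tuple[np.ndarray, tuple[float, float]]:
    """Z-score a column; returns the scores and the recorded ``(mean, sd)``.

    SD uses the n-1 denominator.  A constant column raises
    :class:`DegenerateScaleError`.
    """
    arr = np.asarray(column, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if not np.isfinite(sd) or sd == 0.0:
        raise DegenerateScaleError("column has zero variance; cannot standardize")
    return (arr - mean) / sd, (mean, sd)


@dataclass
class DesignMatrix:
    """Numeric analysis-ready variables for one model family.

    ``columns`` holds predictor, third variables and covariate codes on the
    modelled (post-transform) scale; ``scaling`` records per-column and
    outcome (mean, SD) for standardized-coefficient computation.
    """

    y: np.ndarray
    y_name: str
    columns: dict[str, np.ndarray]
    scaling: dict[str, tuple[float, float]]
    predictor_col: str
    third_cols: tuple[str, ...]
    covariate_cols: tuple[str, ...]
    n: int = 0
    n_dropped: int = 0
    lod_substitutions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.n = len(self.y)
        for name, col in self.columns.items():
            if len(col) != self.n:
                raise ContractError(f"column {name!r} length mismatch")
            if np.isnan(col).any():
                raise ContractError(f"column {name!r} contains missing values")
        if np.isnan(self.y).any():
            raise ContractError("outcome contains missing values")

    def sd(self, name: str) -> float:
        return self.scaling[name][1]

    def subset(self, names) -> dict[str, np.ndarray]:
        return {k: self.columns[k] for k in names}


def resolve_variable(
    cohort: CohortTable,
    var: str,
    transform: str,
    lod_policy: LodPolicy,
    encoded: Mapping[str, np.ndarray],
) -> tuple[str, np.ndarray, int]:
    """Resolve a model variable to (design name, numeric values, #LOD subs)."""
    frame = cohort.frame
    n_sub = 0
    if var in ("cotinine", "crp"):
        values = frame[var].to_numpy(dtype=float)
        below = frame[f"{var}_below_lod"].to_numpy(dtype=bool)
        if transform == "log":
            values, n_sub = log_transform(values, below, lod_policy)
            name = f"log_{var}"
        else:
            if below.any():
                if lod_policy == "strict":
                    raise DomainError("below-LOD values with policy 'strict'")
                values = values.copy()
                values[below] = [lod_substitute(v, lod_policy) for v in values[below]]
                n_sub = int(below.sum())
            name = var
        return name, values, n_sub
    if var == "ltl":
        bp = frame["ltl_bp"].to_numpy(dtype=float)
        ts = frame["ts_ratio"].to_numpy(dtype=float)
        use_ts = np.isnan(bp) & ~np.isnan(ts)
        if use_ts.any():
            bp = bp.copy()
            bp[use_ts] = ts_to_bp(ts[use_ts])
        values = bp
        name = "ltl_bp"
    elif var in ("age", "bmi"):
        values = frame[var].to_numpy(dtype=float)
        name = var
    elif var in ("sex", "race", "physical_activity", "alcohol_use", "current_smoker"):
        name = DESIGN_NAMES[var]
        values = np.asarray(encoded[name], dtype=float)
    else:
        raise ContractError(f"unknown variable {var!r}")
    if transform == "log":
        values, _ = log_transform(values, None, "strict")
        name = f"log_{name}"
    return name, values, n_sub


def build_design(
    cohort: CohortTable,
    spec: ModelSpec,
    lod_policy: LodPolicy = "lod_over_sqrt2",
) -> DesignMatrix:
    """Complete-case filter + transforms + coding for one ModelSpec.

    All sub-models of a third-variable run are later fit on this single
    design so the decomposition identity holds exactly.
    """
    kept, n_dropped = complete_case_filter(cohort, spec)
    encoded = encode_covariates(kept)

    columns: dict[str, np.ndarray] = {}
    scaling: dict[str, tuple[float, float]] = {}
    lod_subs: dict[str, int] = {}

    def add(var: str) -> str:
        name, values, n_sub = resolve_variable(
            kept, var, spec.transform_of(var), lod_policy, encoded
        )
        if n_sub:
            lod_subs[var] = n_sub
        _, (mean, sd) = standardize(values)
        columns[name] = values
        scaling[name] = (mean, sd)
        return name

    predictor_col = add(spec.predictor)
    third_cols = tuple(add(z) for z in spec.third_variables)
    covariate_cols = tuple(add(c) for c in spec.covariates)

    y_name, y, _ = resolve_variable(
        kept, spec.outcome, spec.transform_of(spec.outcome), lod_policy, encoded
    )
    _, (ym, ysd) = standardize(y)
    scaling[y_name] = (ym, ysd)

    return DesignMatrix(
        y=y,
        y_name=y_name,
        columns=columns,
        scaling=scaling,
        predictor_col=predictor_col,
        third_cols=third_cols,
        covariate_cols=covariate_cols,
        n_dropped=n_dropped,
        lod_substitutions=lod_subs,
    )
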