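"""Least-squares core: standardized coefficients with inference, ANCOVA
adjusted means and chi-square descriptives.

Fitting is delegated to :mod:`statsmodels` (classical homoskedastic SEs,
t-based inference on residual df); this module owns the standardization
contract: ``std_beta = raw_beta * SD(x) / SD(y)`` with SEs and CIs scaled by
the same factor and p-values untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    CollinearityError,
    ContractError,
    DegenerateTableError,
)

INTERCEPT = "intercept"


@dataclass(frozen=True)
class Term:
    """One model term on the standardized scale."""

    name: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float

    def to_dict(self) -> dict:
        return {
            "term": self.name,
            "beta": self.beta,
            "se": self.se,
            "ci95": [self.ci_low, self.ci_high],
            "p": self.p,
        }


@dataclass
class RawFit:
    """Unstandardized OLS fit (intercept always included)."""

    names: tuple[str, ...]          # non-intercept columns, design order
    params: dict[str, float]        # includes INTERCEPT
    se: dict[str, float]
    p: dict[str, float]
    df_resid: int
    n: int
    r_squared: float


@dataclass
class StdRegResult:
    """Standardized coefficients for one fitted model."""

    terms: list[Term]
    n: int
    r_squared: float
    df_resid: int
    outcome: str = ""

    def term(self, name: str) -> Term:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.to_dict() for t in self.terms])

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n": self.n,
            "r_squared": self.r_squared,
            "terms": [t.to_dict() for t in self.terms],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_tsv(self) -> str:
        lines = ["term\tbeta\tci_low\tci_high\tp"]
        for t in self.terms:
            lines.append(
                f"{t.name}\t{t.beta:.6g}\t{t.ci_low:.6g}\t{t.ci_high:.6g}\t{t.p:.4g}"
            )
        return "\n".join(lines) + "\n"


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise CollinearityError naming the first dependent column."""
    n = X.shape[0]
    ones = np.ones((n, 1))
    full = np.column_stack([ones, X])
    if np.linalg.matrix_rank(full) == full.shape[1]:
        return
    mat = ones
    for j, name in enumerate(names):
        cand = np.column_stack([mat, X[:, j]])
        if np.linalg.matrix_rank(cand) < cand.shape[1]:
            raise CollinearityError(name)
        mat = cand
    raise CollinearityError("intercept")


def fit_ols(y, columns: Mapping[str, np.ndarray]) -> RawFit:
    """Ordinary least squares of ``y`` on the named columns plus intercept.

    Raises :class:`CollinearityError` for a rank-deficient design, naming the
    first offending column, and :class:`ContractError` when n is too small.
    """
    names = tuple(columns.keys())
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.asarray(columns[k], dtype=float) for k in names]) \
        if names else np.empty((len(y), 0))
    if np.isnan(y).any() or (X.size and np.isnan(X).any()):
        raise ContractError("missing values in regression inputs")
    if len(y) <= X.shape[1] + 1:
        raise ContractError(
            f"n={len(y)} too small for {X.shape[1]} predictors plus intercept"
        )
    if names:
        _check_rank(X, names)
    exog = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, exog).fit()
    keys = (INTERCEPT,) + names
    return RawFit(
        names=names,
        params=dict(zip(keys, fit.params)),
        se=dict(zip(keys, fit.bse)),
        p=dict(zip(keys, fit.pvalues)),
        df_resid=int(fit.df_resid),
        n=len(y),
        r_squared=float(fit.rsquared) if names else 0.0,
    )


def standardized_betas(
    raw: RawFit,
    scaling: Mapping[str, tuple[float, float]],
    y_name: str,
    level: float = 0.95,
) -> StdRegResult:
    """Rescale a raw fit to standardized coefficients.

    Every non-intercept term (binary indicators included) is scaled by
    ``SD(term)/SD(outcome)``; CIs use the t distribution on residual df;
    p-values carry over from the raw fit unchanged.
    """
    if y_name not in scaling:
        raise ContractError(f"no recorded scaling for outcome {y_name!r}")
    sd_y = scaling[y_name][1]
    tcrit = stats.t.ppf(0.5 + level / 2.0, raw.df_resid)
    terms = []
    for name in raw.names:
        if name not in scaling:
            raise ContractError(f"no recorded scaling for term {name!r}")
        factor = scaling[name][1] / sd_y
        beta = raw.params[name] * factor
        se = raw.se[name] * factor
        terms.append(
            Term(
                name=name,
                beta=beta,
                se=se,
                ci_low=beta - tcrit * se,
                ci_high=beta + tcrit * se,
                p=raw.p[name],
            )
        )
    return StdRegResult(
        terms=terms,
        n=raw.n,
        r_squared=raw.r_squared,
        df_resid=raw.df_resid,
        outcome=y_name,
    )


@dataclass
class AdjustedMeansResult:
    """Covariate-adjusted (least-squares) group means."""

    means: dict[str, float]
    p: float
    group_sizes: dict[str, int] = field(default_factory=dict)


def adjusted_means(outcome, group, adjuster) -> AdjustedMeansResult:
    """ANCOVA-adjusted means: LS means at the grand mean of the adjuster.

    The p-value is the F-test of the group factor (full vs adjuster-only
    model).  Requires at least two groups with two members each.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group)
    a = np.asarray(adjuster, dtype=float)
    levels = [lv for lv in pd.unique(g)]
    if len(levels) < 2:
        raise ContractError("adjusted_means requires at least two groups")
    sizes = {str(lv): int((g == lv).sum()) for lv in levels}
    if min(sizes.values()) < 2:
        raise ContractError("each group needs at least two members")

    dummies = {f"g_{lv}": (g == lv).astype(float) for lv in levels[1:]}
    cols = dict(dummies)
    cols["adjuster"] = a
    full = fit_ols(y, cols)
    reduced = fit_ols(y, {"adjuster": a})

    # F test from R^2 difference (same y, nested models)
    df_num = len(levels) - 1
    df_den = full.df_resid
    ss_tot = float(((y - y.mean()) ** 2).sum())
    rss_full = ss_tot * (1.0 - full.r_squared)
    rss_red = ss_tot * (1.0 - reduced.r_squared)
    if rss_full <= 0:
        f_stat = np.inf
        p = 0.0
    else:
        f_stat = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
        f_stat = max(f_stat, 0.0)
        p = float(stats.f.sf(f_stat, df_num, df_den))

    a_bar = float(a.mean())
    base = full.params[INTERCEPT] + full.params["adjuster"] * a_bar
    means = {str(levels[0]): base}
    for lv in levels[1:]:
        means[str(lv)] = base + full.params[f"g_{lv}"]
    return AdjustedMeansResult(means=means, p=p, group_sizes=sizes)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float


def chi_square_test(table) -> ChiSquareResult:
    """Pearson chi-square test of independence on a contingency table."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or min(tab.shape) < 2:
        raise ContractError("contingency table must be at least 2x2")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise DegenerateTableError("contingency table has a zero marginal")
    stat, p, df, expected = stats.chi2_contingency(tab, correction=False)
    if (expected <= 0).any():
        raise DegenerateTableError("expected count of zero")
    return ChiSquareResult(statistic=float(stat), df=int(df), p=float(p))
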