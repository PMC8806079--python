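"""Path-difference testing between two groups and predictor-swap
sensitivity analysis.

Each path of the decomposition (total effect, X->Z_k, Z_k->Y, direct
effect) is tested in its own pooled interaction model: the group indicator
is always present as a main effect and a single (path predictor x group)
product term supplies the interaction p-value.  Per-group coefficients are
reported from stratified fits, standardized within stratum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .datamodel import CohortTable, ModelSpec
from .decompose import ThirdVarResult, run_third_variable_analysis
from .errors import ContractError, InsufficientGroupError
from .preprocess import LodPolicy, build_design
from .regression import Term, fit_ols, standardized_betas

#: group variable -> (cohort column, indicator design name, level coded 1)
_GROUP_CODING = {
    "race": ("race", "black_race", "black"),
    "sex": ("sex", "female_sex", "female"),
    "current_smoker": ("current_smoker", "current_smoker", True),
}


@dataclass
class GroupComparison:
    """One path compared between two groups."""

    path: str                     # e.g. "total", "x_to_bmi", "bmi_to_y", "direct"
    group_var: str
    groups: tuple[str, str]
    betas: dict[str, Term]        # per-group standardized coefficient
    interaction_p: float
    interaction_beta: float
    n_per_group: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "path": self.path,
            "group_var": self.group_var,
            "groups": list(self.groups),
            "betas": {g: t.to_dict() for g, t in self.betas.items()},
            "interaction_p": self.interaction_p,
            "interaction_beta": self.interaction_beta,
            "n_per_group": dict(self.n_per_group),
        }


def _path_model(spec: ModelSpec, path: str) -> tuple[str, str, tuple[str, ...]]:
    """Resolve a path label to (outcome var, focal predictor var, extra Zs).

    ``extra Zs`` are third variables included alongside the focal predictor
    (the outcome-model paths condition on all Zs).
    """
    zs = spec.third_variables
    if path == "total":
        return spec.outcome, spec.predictor, ()
    if path == "direct":
        return spec.outcome, spec.predictor, zs
    for z in zs:
        if path == f"x_to_{z}":
            return z, spec.predictor, ()
        if path == f"{z}_to_y":
            return spec.outcome, z, zs
    raise ContractError(f"unknown path {path!r} for this model spec")


def _split_cohort(cohort: CohortTable, column: str, levels) -> dict[str, CohortTable]:
    out = {}
    for lv in levels:
        mask = (cohort.frame[column] == lv).to_numpy()
        if mask.sum() > 0:
            out[str(lv)] = CohortTable(cohort.frame.loc[mask].copy(), cohort.provenance)
    return out


def interaction_test(
    spec: ModelSpec,
    cohort: CohortTable,
    group_var: str,
    path: str,
    lod_policy: LodPolicy = "lod_over_sqrt2",
    min_group_n: int = 50,
    full_interactions: bool = False,
) -> GroupComparison:
    """Test whether one standardized path differs between two groups.

    The pooled model keeps the group main effect and adds the
    (focal predictor x group) product; with ``full_interactions=True`` every
    covariate (and co-included Z) is also interacted with the group, which
    makes the pooled fit reproduce the stratified fits exactly.
    """
    if group_var not in _GROUP_CODING:
        raise ContractError(
            f"group_var must be one of {sorted(_GROUP_CODING)}, got {group_var!r}"
        )
    column, indicator, one_level = _GROUP_CODING[group_var]
    outcome_var, focal_var, extra_zs = _path_model(spec, path)

    # model spec for this path: focal predictor first, co-included Zs,
    # covariates without the group variable itself
    covs = tuple(c for c in spec.covariates if c != group_var)
    zs_in_model = tuple(z for z in extra_zs if z != focal_var)
    path_spec = ModelSpec(
        predictor=focal_var,
        outcome=outcome_var,
        third_variables=zs_in_model,
        covariates=covs,
        transforms=spec.transforms,
    )

    # shared complete-case sample over model variables AND the group column
    union_spec = ModelSpec(
        predictor=focal_var,
        outcome=outcome_var,
        third_variables=zs_in_model,
        covariates=covs + ((group_var,) if group_var not in covs else ()),
        transforms=spec.transforms,
    )
    from .preprocess import complete_case_filter

    shared, _ = complete_case_filter(cohort, union_spec)

    levels = [lv for lv in shared.frame[column].unique()]
    if len(levels) != 2:
        raise InsufficientGroupError(
            f"{group_var!r} must take exactly two values in the sample, found {levels}"
        )
    # order groups: reference (coded 0) first
    levels = sorted(levels, key=lambda lv: lv == one_level)
    strata = _split_cohort(shared, column, levels)
    sizes = {g: len(t) for g, t in strata.items()}
    if min(sizes.values()) < min_group_n:
        raise InsufficientGroupError(
            f"group sizes {sizes} below minimum {min_group_n}"
        )

    # per-group standardized betas from stratified fits
    betas: dict[str, Term] = {}
    for g, sub in strata.items():
        design = build_design(sub, path_spec, lod_policy)
        cols = design.subset(
            (design.predictor_col,) + design.third_cols + design.covariate_cols
        )
        raw = fit_ols(design.y, cols)
        res = standardized_betas(raw, design.scaling, design.y_name)
        betas[g] = res.term(design.predictor_col)

    # pooled model with group main effect + focal-by-group interaction
    pooled = build_design(shared, union_spec, lod_policy)
    gcol = pooled.columns[indicator]
    cols = dict(pooled.subset(
        (pooled.predictor_col,) + pooled.third_cols + pooled.covariate_cols
    ))
    if indicator not in cols:
        cols[indicator] = gcol
    inter_name = f"{pooled.predictor_col}:{indicator}"
    cols[inter_name] = pooled.columns[pooled.predictor_col] * gcol
    if full_interactions:
        for name in pooled.third_cols + pooled.covariate_cols:
            if name == indicator:
                continue
            cols[f"{name}:{indicator}"] = pooled.columns[name] * gcol
    raw = fit_ols(pooled.y, cols)

    return GroupComparison(
        path=path,
        group_var=group_var,
        groups=(str(levels[0]), str(levels[1])),
        betas=betas,
        interaction_p=raw.p[inter_name],
        interaction_beta=raw.params[inter_name],
        n_per_group=sizes,
    )


#: Table layout of a full subgroup run: total, per-Z action/outcome paths,
#: direct effect.
def _all_paths(spec: ModelSpec) -> list[str]:
    paths = ["total"]
    for z in spec.third_variables:
        paths.append(f"x_to_{z}")
        paths.append(f"{z}_to_y")
    paths.append("direct")
    return paths


def run_subgroup_table(
    spec: ModelSpec,
    cohort: CohortTable,
    group_var: str,
    lod_policy: LodPolicy = "lod_over_sqrt2",
    min_group_n: int = 50,
) -> list[GroupComparison]:
    """All decomposition paths compared between the two groups."""
    return [
        interaction_test(spec, cohort, group_var, path, lod_policy, min_group_n)
        for path in _all_paths(spec)
    ]


def subgroup_table_tsv(rows: list[GroupComparison]) -> str:
    """Render subgroup comparisons: rows = paths, columns = groups + p."""
    if not rows:
        return ""
    g0, g1 = rows[0].groups
    lines = [
        "path\t" + f"beta_{g0}\tp_{g0}\tbeta_{g1}\tp_{g1}\tinteraction_p"
    ]
    for r in rows:
        t0, t1 = r.betas[g0], r.betas[g1]
        lines.append(
            f"{r.path}\t{t0.beta:.6g}\t{t0.p:.4g}\t{t1.beta:.6g}\t{t1.p:.4g}"
            f"\t{r.interaction_p:.4g}"
        )
    return "\n".join(lines) + "\n"


@dataclass
class SensitivityResult:
    """Side-by-side third-variable results for two predictors."""

    original: ThirdVarResult
    swapped: ThirdVarResult
    sign_agreement: dict[str, bool]

    def to_dict(self) -> dict:
        return {
            "original": self.original.to_dict(),
            "swapped": self.swapped.to_dict(),
            "sign_agreement": dict(self.sign_agreement),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def sensitivity_swap_predictor(
    spec: ModelSpec,
    cohort: CohortTable,
    new_predictor: str,
    lod_policy: LodPolicy = "lod_over_sqrt2",
) -> SensitivityResult:
    """Re-run the full analysis with the predictor replaced.

    Returns both results with a per-term sign-agreement summary (total,
    direct, and per-Z action/outcome paths).
    """
    original = run_third_variable_analysis(spec, cohort, lod_policy)
    if new_predictor == spec.predictor:
        swapped = original
    else:
        transforms = {k: v for k, v in dict(spec.transforms).items()
                      if k != spec.predictor}
        new_spec = spec.replace(predictor=new_predictor, transforms=transforms)
        swapped = run_third_variable_analysis(new_spec, cohort, lod_policy)

    def sign(x: float) -> float:
        return math.copysign(1.0, x) if x != 0 else 0.0

    agree = {
        "total": sign(original.paths.c.beta) == sign(swapped.paths.c.beta),
        "direct": sign(original.paths.c_prime.beta) == sign(swapped.paths.c_prime.beta),
    }
    for z in spec.third_variables:
        agree[f"x_to_{z}"] = sign(original.paths.beta1[z].beta) == sign(
            swapped.paths.beta1[z].beta
        )
        agree[f"{z}_to_y"] = sign(original.paths.beta2[z].beta) == sign(
            swapped.paths.beta2[z].beta
        )
    return SensitivityResult(original=original, swapped=swapped, sign_agreement=agree)
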