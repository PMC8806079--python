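"""Four-step third-variable decomposition with mediation/suppression
classification.

For predictor X, outcome Y, intermediates Z_k and covariates C, all fit on
one shared complete-case sample and standardized with that sample's SDs:

1. total effect       c      from  Y ~ X + C
2. action paths       beta1_k from  Z_k ~ X + C          (other Zs excluded)
3. outcome model      c', beta2_k from  Y ~ X + Z_1..Z_K + C
4. classification by comparing |c| and |c'| (defined when |c| > |beta_Ind|),
   with effect percentages |beta_Ind|/|c| (mediation) or |beta_Ind|/|c'|
   (suppression).

Because every sub-model shares the sample and the scaling, the identity
``c = c' + sum_k beta1_k * beta2_k`` holds to machine precision.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field

from scipy import stats

from .datamodel import CohortTable, ModelSpec
from .errors import ContractError, DomainError, UndefinedStatisticError
from .preprocess import DesignMatrix, LodPolicy, build_design
from .regression import StdRegResult, Term, fit_ols, standardized_betas


class Role(str, enum.Enum):
    MEDIATION = "mediation"
    SUPPRESSION = "suppression"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class SobelResult:
    """Delta-method z-test of an indirect-effect product."""

    z: float
    p: float
    se: float


@dataclass
class PathEstimates:
    """Standardized path coefficients of one decomposition."""

    c: Term
    c_prime: Term
    beta1: dict[str, Term]
    beta2: dict[str, Term]

    @property
    def indirect(self) -> dict[str, float]:
        return {
            z: indirect_effect(self.beta1[z].beta, self.beta2[z].beta)
            for z in self.beta1
        }

    @property
    def indirect_overall(self) -> float:
        return sum(self.indirect.values())

    @property
    def identity_gap(self) -> float:
        """|c - c' - sum_k beta1_k beta2_k|; ~0 on a shared sample."""
        return abs(self.c.beta - self.c_prime.beta - self.indirect_overall)


@dataclass
class ThirdVarResult:
    """Full output of one third-variable analysis."""

    spec: ModelSpec
    n: int
    n_dropped: int
    paths: PathEstimates
    roles: dict[str, Role]
    effect_percents: dict[str, float]
    sobel: dict[str, SobelResult]
    sobel_overall: SobelResult
    models: dict[str, StdRegResult] = field(default_factory=dict)
    lod_substitutions: dict[str, int] = field(default_factory=dict)

    @property
    def identity_gap(self) -> float:
        return self.paths.identity_gap

    def to_dict(self) -> dict:
        p = self.paths
        return {
            "predictor": self.spec.predictor,
            "outcome": self.spec.outcome,
            "third_variables": list(self.spec.third_variables),
            "covariates": list(self.spec.covariates),
            "n": self.n,
            "n_dropped": self.n_dropped,
            "total_effect": p.c.to_dict(),
            "direct_effect": p.c_prime.to_dict(),
            "paths": {
                z: {
                    "beta1": p.beta1[z].to_dict(),
                    "beta2": p.beta2[z].to_dict(),
                    "indirect": p.indirect[z],
                    "role": self.roles[z].value,
                    "effect_percent": self.effect_percents[z],
                    "sobel_z": self.sobel[z].z,
                    "sobel_p": self.sobel[z].p,
                }
                for z in p.beta1
            },
            "indirect_overall": p.indirect_overall,
            "sobel_overall": {"z": self.sobel_overall.z, "p": self.sobel_overall.p},
            "identity_gap": p.identity_gap,
            "lod_substitutions": dict(self.lod_substitutions),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_tsv(self) -> str:
        """Flat machine-readable path table (one row per path coefficient)."""
        p = self.paths
        lines = ["path\tlabel\tbeta\tse\tci_low\tci_high\tp"]

        def row(path, t: Term):
            lines.append(
                f"{path}\t{t.name}\t{t.beta:.10g}\t{t.se:.10g}"
                f"\t{t.ci_low:.10g}\t{t.ci_high:.10g}\t{t.p:.6g}"
            )

        row("total", p.c)
        row("direct", p.c_prime)
        for z in p.beta1:
            row(f"x_to_{z}", p.beta1[z])
            row(f"{z}_to_y", p.beta2[z])
            lines.append(
                f"indirect_{z}\t{z}\t{p.indirect[z]:.10g}\t{self.sobel[z].se:.10g}"
                f"\t\t\t{self.sobel[z].p:.6g}"
            )
        lines.append(
            f"indirect_overall\t\t{p.indirect_overall:.10g}"
            f"\t{self.sobel_overall.se:.10g}\t\t\t{self.sobel_overall.p:.6g}"
        )
        return "\n".join(lines) + "\n"


def total_effect(design: DesignMatrix) -> tuple[Term, StdRegResult]:
    """Step 1: standardized coefficient of X from Y ~ X + covariates."""
    cols = design.subset((design.predictor_col,) + design.covariate_cols)
    raw = fit_ols(design.y, cols)
    res = standardized_betas(raw, design.scaling, design.y_name)
    return res.term(design.predictor_col), res


def path_a(design: DesignMatrix, z_col: str) -> tuple[Term, StdRegResult]:
    """Step 2: standardized coefficient of X from Z_k ~ X + covariates."""
    if z_col not in design.third_cols:
        raise ContractError(f"{z_col!r} is not a third variable of this design")
    cols = design.subset((design.predictor_col,) + design.covariate_cols)
    raw = fit_ols(design.columns[z_col], cols)
    # outcome here is Z_k: reuse recorded scalings with z as outcome
    res = standardized_betas(raw, design.scaling, z_col)
    return res.term(design.predictor_col), res


def outcome_model(design: DesignMatrix) -> StdRegResult:
    """Step 3: Y ~ X + all Zs + covariates (standardized)."""
    cols = design.subset(
        (design.predictor_col,) + design.third_cols + design.covariate_cols
    )
    raw = fit_ols(design.y, cols)
    return standardized_betas(raw, design.scaling, design.y_name)


def indirect_effect(beta1: float, beta2: float) -> float:
    """Product-of-coefficients indirect effect."""
    return beta1 * beta2


def sobel_test(
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    second_order: bool = False,
) -> SobelResult:
    """Delta-method z-test of ``beta1 * beta2``.

    First-order SE ``sqrt(b1^2 se2^2 + b2^2 se1^2)``; with
    ``second_order=True`` the ``se1^2 se2^2`` term is added.
    """
    if se1 <= 0 or se2 <= 0:
        raise ContractError("sobel_test requires positive standard errors")
    var = beta1 ** 2 * se2 ** 2 + beta2 ** 2 * se1 ** 2
    if second_order:
        var += se1 ** 2 * se2 ** 2
    se = math.sqrt(var)
    if se == 0.0:
        raise UndefinedStatisticError("indirect-effect SE is zero")
    z = beta1 * beta2 / se
    return SobelResult(z=z, p=float(2.0 * stats.norm.sf(abs(z))), se=se)


def _sobel_overall(
    beta1: dict[str, Term], beta2: dict[str, Term], second_order: bool = False
) -> SobelResult:
    """Delta-method test of the summed indirect effect.

    Cross-path covariances are ignored (paths treated as independent),
    matching the per-path first-order approximation.
    """
    var = 0.0
    total = 0.0
    for z in beta1:
        b1, s1 = beta1[z].beta, beta1[z].se
        b2, s2 = beta2[z].beta, beta2[z].se
        total += b1 * b2
        var += b1 ** 2 * s2 ** 2 + b2 ** 2 * s1 ** 2
        if second_order:
            var += s1 ** 2 * s2 ** 2
    se = math.sqrt(var)
    if se == 0.0:
        raise UndefinedStatisticError("overall indirect-effect SE is zero")
    zstat = total / se
    return SobelResult(z=zstat, p=float(2.0 * stats.norm.sf(abs(zstat))), se=se)


def classify(c: float, c_prime: float, indirect: float) -> Role:
    """Step 4: mediation vs suppression by magnitude comparison.

    Defined only when ``|c| > |indirect|``; otherwise ``UNDEFINED``.  The
    exact tie ``|c| == |c'|`` resolves to mediation when the indirect effect
    carries the sign of c, suppression otherwise (deterministic tie-break).
    """
    if abs(c) <= abs(indirect):
        return Role.UNDEFINED
    if abs(c) > abs(c_prime):
        return Role.MEDIATION
    if abs(c) < abs(c_prime):
        return Role.SUPPRESSION
    return Role.MEDIATION if math.copysign(1.0, indirect) == math.copysign(1.0, c) \
        else Role.SUPPRESSION


def effect_percent(role: Role, indirect: float, c: float, c_prime: float) -> float:
    """Mediation % = |ind|/|c| * 100; suppression % = |ind|/|c'| * 100."""
    if role is Role.UNDEFINED:
        warnings.warn("effect percentage undefined for role 'undefined'", stacklevel=2)
        return math.nan
    denom = abs(c) if role is Role.MEDIATION else abs(c_prime)
    if denom == 0.0:
        raise DomainError("zero denominator in effect percentage")
    return abs(indirect) / denom * 100.0


def _per_z_role(indirect_k: float, c: float, c_prime: float, n_z: int) -> Role:
    """Role attribution for one Z.

    Single Z: the magnitude rule on (c, c').  Two Zs: sign of the component
    relative to c (same sign -> mediation-type, opposite -> suppression-type).
    """
    if n_z == 1:
        return classify(c, c_prime, indirect_k)
    if indirect_k == 0.0:
        return Role.MEDIATION
    if abs(c) <= abs(indirect_k):
        return Role.UNDEFINED
    same_sign = math.copysign(1.0, indirect_k) == math.copysign(1.0, c)
    return Role.MEDIATION if same_sign else Role.SUPPRESSION


def run_third_variable_analysis(
    spec: ModelSpec,
    cohort: CohortTable,
    lod_policy: LodPolicy = "lod_over_sqrt2",
    second_order_sobel: bool = False,
) -> ThirdVarResult:
    """Run steps 1-4 on a shared complete-case sample.

    Complete-case filtering happens once, on the union of every variable in
    ``spec``, so that all sub-models see identical rows and the
    decomposition identity holds exactly.
    """
    if not 1 <= len(spec.third_variables) <= 2:
        raise ContractError("analysis requires one or two third variables")
    design = build_design(cohort, spec, lod_policy)

    c, total_model = total_effect(design)
    full = outcome_model(design)
    c_prime = full.term(design.predictor_col)

    beta1: dict[str, Term] = {}
    beta2: dict[str, Term] = {}
    z_models: dict[str, StdRegResult] = {}
    for var, col in zip(spec.third_variables, design.third_cols):
        b1, model = path_a(design, col)
        beta1[var] = b1
        beta2[var] = full.term(col)
        z_models[f"z_{var}"] = model

    paths = PathEstimates(c=c, c_prime=c_prime, beta1=beta1, beta2=beta2)
    if paths.identity_gap > 1e-8:
        raise ContractError(
            f"decomposition identity violated (gap={paths.identity_gap:.3e}); "
            "sub-models were not fit on a shared sample"
        )

    n_z = len(spec.third_variables)
    roles = {}
    percents = {}
    sobel = {}
    for var in spec.third_variables:
        ind_k = paths.indirect[var]
        role = _per_z_role(ind_k, c.beta, c_prime.beta, n_z)
        roles[var] = role
        percents[var] = (
            math.nan if role is Role.UNDEFINED
            else effect_percent(role, ind_k, c.beta, c_prime.beta)
        )
        sobel[var] = sobel_test(
            beta1[var].beta, beta1[var].se, beta2[var].beta, beta2[var].se,
            second_order=second_order_sobel,
        )
    overall = _sobel_overall(beta1, beta2, second_order=second_order_sobel)

    models = {"total": total_model, "outcome": full, **z_models}
    return ThirdVarResult(
        spec=spec,
        n=design.n,
        n_dropped=design.n_dropped,
        paths=paths,
        roles=roles,
        effect_percents=percents,
        sobel=sobel,
        sobel_overall=overall,
        models=models,
        lod_substitutions=design.lod_substitutions,
    )
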