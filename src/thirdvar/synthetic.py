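"""Seeded generator of synthetic cohorts with a known linear structure,
plus an analytic oracle for the implied standardized path coefficients.

The generator draws covariates independently, then builds log-cotinine (a
smoker/non-smoker mixture on the log scale), BMI, log-CRP and telomere
length from linear structural equations with Gaussian noise.  Because the
equations are linear in independent shocks, the population covariance
matrix — and hence every population least-squares standardized coefficient —
is available in closed form (:func:`implied_standardized_paths`), which is
what makes the generator usable as a test oracle.

Default path coefficients are tuned (see ``scripts/tune_generator.py``) so
that fitted standardized coefficients at realistic sample sizes land close
to the reference magnitudes the analysis is meant to reproduce: a negative
exposure->BMI path, positive exposure->CRP path, negative BMI->LTL and
CRP->LTL paths and a negative direct path, which jointly produce the
suppression (BMI) / mediation (CRP) sign pattern.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import ACTIVITY_LEVELS, ALCOHOL_LEVELS, CohortTable
from .errors import ConfigError
from .preprocess import bp_to_ts

#: Independent exogenous shocks, in a fixed order.
_SHOCKS = (
    "age", "female", "black", "active", "alcohol", "smoker",
    "e_x", "e_bmi", "e_crp", "e_y",
)

#: Allowed predictor keys per structural equation.
_EQ_KEYS = {
    "x_eq": {"const", "noise_sd", "smoker", "age", "female", "black",
             "active", "alcohol"},
    "bmi_eq": {"const", "noise_sd", "x", "age", "female", "black",
               "active", "alcohol", "smoker"},
    "crp_eq": {"const", "noise_sd", "x", "age", "female", "black",
               "active", "alcohol", "smoker"},
    "y_eq": {"const", "noise_sd", "x", "bmi", "crp", "age", "female",
             "black", "active", "alcohol", "smoker"},
}


def _default_x_eq() -> dict:
    return {
        "const": -1.6,       # non-smoker geometric mean ~0.2 ng/mL
        "smoker": 5.2,       # smokers elevated by ~e^5 in natural units
        "age": -0.15,
        "female": -0.30,
        "black": 0.40,
        "noise_sd": 1.10,
    }


def _default_bmi_eq() -> dict:
    # slopes solved by scripts/tune_generator.py
    return {
        "const": 28.8,
        "x": -0.175217,
        "age": 0.55,
        "female": 0.60,
        "black": 1.80,
        "noise_sd": 5.60,
    }


def _default_crp_eq() -> dict:
    return {
        "const": -1.25,
        "x": 0.041815,
        "age": 0.18,
        "female": 0.32,
        "black": 0.16,
        "noise_sd": 0.95,
    }


def _default_y_eq() -> dict:
    return {
        "const": 6120.0,
        "x": -11.082733,
        "bmi": -3.997497,
        "crp": -39.160983,
        "age": -244.46643,
        "female": 78.639684,
        "black": 120.213424,
        "active": 51.415034,
        "alcohol": 24.018655,
        "noise_sd": 575.0,
    }


@dataclass
class SyntheticParams:
    """Structural parameters of the synthetic cohort generator.

    Continuous equations are expressed on the modelled scales (log ng/mL for
    cotinine, log mg/dL for CRP, kg/m^2 for BMI, base pairs for LTL) with
    ``age`` entering as standardized age.  ``ltl_output`` selects which
    telomere column(s) the cohort carries: ``"bp"``, ``"ts"`` or ``"both"``.
    """

    n: int = 4047
    seed: int = 0
    female_frac: float = 0.474
    black_frac: float = 0.231
    activity_probs: tuple[float, ...] = (0.585, 0.283, 0.132)
    alcohol_probs: tuple[float, ...] = (0.316, 0.409, 0.134, 0.141)
    smoking_prevalence: float = 0.27
    age_range: tuple[float, float] = (20.0, 85.0)
    lod_cotinine: float = 0.015
    ltl_output: str = "bp"
    x_eq: dict = field(default_factory=_default_x_eq)
    bmi_eq: dict = field(default_factory=_default_bmi_eq)
    crp_eq: dict = field(default_factory=_default_crp_eq)
    y_eq: dict = field(default_factory=_default_y_eq)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be positive")
        for name, p in (("female_frac", self.female_frac),
                        ("black_frac", self.black_frac),
                        ("smoking_prevalence", self.smoking_prevalence)):
            if not 0.0 < p < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1)")
        for name, probs, k in (("activity_probs", self.activity_probs, 3),
                               ("alcohol_probs", self.alcohol_probs, 4)):
            if len(probs) != k or abs(sum(probs) - 1.0) > 1e-9 or min(probs) <= 0:
                raise ConfigError(f"{name} must be {k} positive values summing to 1")
        lo, hi = self.age_range
        if not (18.0 <= lo < hi <= 120.0):
            raise ConfigError("age_range must be increasing within [18, 120]")
        if self.lod_cotinine <= 0:
            raise ConfigError("lod_cotinine must be positive")
        if self.ltl_output not in ("bp", "ts", "both"):
            raise ConfigError("ltl_output must be 'bp', 'ts' or 'both'")
        for eq_name in ("x_eq", "bmi_eq", "crp_eq", "y_eq"):
            eq = getattr(self, eq_name)
            unknown = set(eq) - _EQ_KEYS[eq_name]
            if unknown:
                raise ConfigError(f"unknown keys in {eq_name}: {sorted(unknown)}")
            if eq.get("noise_sd", 0.0) <= 0.0:
                raise ConfigError(f"{eq_name} noise_sd must be positive")

    def replace(self, **kwargs) -> "SyntheticParams":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["activity_probs"] = list(self.activity_probs)
        d["alcohol_probs"] = list(self.alcohol_probs)
        d["age_range"] = list(self.age_range)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticParams":
        d = yaml.safe_load(text)
        for key in ("activity_probs", "alcohol_probs", "age_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _bernoulli_var(p: float) -> float:
    return p * (1.0 - p)


def _categorical_var(probs, scores) -> float:
    probs = np.asarray(probs, dtype=float)
    scores = np.asarray(scores, dtype=float)
    mean = float((probs * scores).sum())
    return float((probs * scores ** 2).sum() - mean ** 2)


def _shock_variances(params: SyntheticParams) -> np.ndarray:
    p_active = params.activity_probs[1] + params.activity_probs[2]
    return np.array([
        1.0,                                             # standardized age
        _bernoulli_var(params.female_frac),
        _bernoulli_var(params.black_frac),
        _bernoulli_var(p_active),
        _categorical_var(params.alcohol_probs, range(4)),
        _bernoulli_var(params.smoking_prevalence),
        params.x_eq["noise_sd"] ** 2,
        params.bmi_eq["noise_sd"] ** 2,
        params.crp_eq["noise_sd"] ** 2,
        params.y_eq["noise_sd"] ** 2,
    ])


def _loadings(params: SyntheticParams) -> dict[str, np.ndarray]:
    """Each variable as a linear combination of the independent shocks."""
    idx = {s: i for i, s in enumerate(_SHOCKS)}

    def base(name: str) -> np.ndarray:
        v = np.zeros(len(_SHOCKS))
        v[idx[name]] = 1.0
        return v

    L: dict[str, np.ndarray] = {
        "age": base("age"),
        "female_sex": base("female"),
        "black_race": base("black"),
        "active_pa": base("active"),
        "alcohol_use": base("alcohol"),
        "current_smoker": base("smoker"),
    }
    shock_of = {"age": "age", "female": "female", "black": "black",
                "active": "active", "alcohol": "alcohol", "smoker": "smoker"}

    def build(eq: dict, noise: str, upstream: dict[str, str]) -> np.ndarray:
        v = base(noise)
        for key, coef in eq.items():
            if key in ("const", "noise_sd"):
                continue
            if key in shock_of:
                v = v + coef * base(shock_of[key])
            else:
                v = v + coef * L[upstream[key]]
        return v

    L["log_cotinine"] = build(params.x_eq, "e_x", {})
    L["bmi"] = build(params.bmi_eq, "e_bmi", {"x": "log_cotinine"})
    L["log_crp"] = build(params.crp_eq, "e_crp", {"x": "log_cotinine"})
    L["ltl_bp"] = build(
        params.y_eq, "e_y",
        {"x": "log_cotinine", "bmi": "bmi", "crp": "log_crp"},
    )
    return L


def implied_covariance(params: SyntheticParams) -> tuple[list[str], np.ndarray]:
    """Population covariance matrix of all model variables."""
    L = _loadings(params)
    v = _shock_variances(params)
    names = list(L.keys())
    mat = np.array([L[n] for n in names])
    sigma = mat @ np.diag(v) @ mat.T
    eig = np.linalg.eigvalsh(sigma)
    if eig.min() <= 0:
        raise ConfigError("implied covariance is not positive definite")
    return names, sigma


#: Design-column covariate names matching the default ModelSpec.
DEFAULT_ORACLE_COVARIATES = (
    "age", "black_race", "female_sex", "active_pa", "alcohol_use",
)

_Z_COLUMN = {"bmi": "bmi", "crp": "log_crp"}


@dataclass
class ImpliedPaths:
    """Population (analytic) standardized path coefficients."""

    c: float
    c_prime: float
    beta1: dict[str, float]
    beta2: dict[str, float]
    outcome_betas: dict[str, float]

    @property
    def indirect(self) -> dict[str, float]:
        return {z: self.beta1[z] * self.beta2[z] for z in self.beta1}

    @property
    def indirect_overall(self) -> float:
        return sum(self.indirect.values())

    @property
    def identity_gap(self) -> float:
        return abs(self.c - self.c_prime - self.indirect_overall)


def _population_std_betas(
    names: list[str], sigma: np.ndarray, outcome: str, predictors: list[str]
) -> dict[str, float]:
    idx = {n: i for i, n in enumerate(names)}
    P = [idx[p] for p in predictors]
    yi = idx[outcome]
    b = np.linalg.solve(sigma[np.ix_(P, P)], sigma[P, yi])
    sd = np.sqrt(np.diag(sigma))
    return {
        p: float(b[k] * sd[idx[p]] / sd[yi]) for k, p in enumerate(predictors)
    }


def implied_standardized_paths(
    params: SyntheticParams,
    third_variables: tuple[str, ...] = ("bmi", "crp"),
    covariates: tuple[str, ...] = DEFAULT_ORACLE_COVARIATES,
) -> ImpliedPaths:
    """Closed-form population values of c, c', beta1_k and beta2_k.

    Computed from the implied covariance matrix by population least squares;
    satisfies ``c = c' + sum_k beta1_k beta2_k`` exactly (linear projection
    algebra).
    """
    for z in third_variables:
        if z not in _Z_COLUMN:
            raise ConfigError(f"unknown third variable {z!r}")
    names, sigma = implied_covariance(params)
    x = "log_cotinine"
    y = "ltl_bp"
    covs = list(covariates)

    c = _population_std_betas(names, sigma, y, [x] + covs)[x]
    beta1 = {}
    for z in third_variables:
        beta1[z] = _population_std_betas(
            names, sigma, _Z_COLUMN[z], [x] + covs
        )[x]
    z_cols = [_Z_COLUMN[z] for z in third_variables]
    full = _population_std_betas(names, sigma, y, [x] + z_cols + covs)
    beta2 = {z: full[_Z_COLUMN[z]] for z in third_variables}
    return ImpliedPaths(
        c=c, c_prime=full[x], beta1=beta1, beta2=beta2, outcome_betas=full
    )


def generate_cohort(params: SyntheticParams) -> CohortTable:
    """Draw one cohort; the same params + seed yield an identical table.

    One seed sequence is spawned into per-variable substreams (documented
    order: age, sex, race, activity, alcohol, smoker, x, bmi, crp, y) so a
    variable's draws do not depend on how other variables are configured.
    """
    n = params.n
    ss = np.random.SeedSequence(params.seed)
    streams = [np.random.default_rng(child) for child in ss.spawn(10)]
    (r_age, r_sex, r_race, r_act, r_alc, r_smk, r_x, r_bmi, r_crp, r_y) = streams

    lo, hi = params.age_range
    age = r_age.uniform(lo, hi, size=n)
    age_std = (age - (lo + hi) / 2.0) / ((hi - lo) / math.sqrt(12.0))
    female = (r_sex.random(n) < params.female_frac).astype(float)
    black = (r_race.random(n) < params.black_frac).astype(float)
    activity = r_act.choice(len(ACTIVITY_LEVELS), size=n, p=params.activity_probs)
    active = (activity > 0).astype(float)
    alcohol = r_alc.choice(4, size=n, p=params.alcohol_probs).astype(float)
    smoker = (r_smk.random(n) < params.smoking_prevalence).astype(float)

    shocks = {
        "age": age_std, "female": female, "black": black,
        "active": active, "alcohol": alcohol, "smoker": smoker,
    }

    def equation(eq: dict, noise_rng, upstream: dict[str, np.ndarray]) -> np.ndarray:
        out = np.full(n, eq["const"], dtype=float)
        for key, coef in eq.items():
            if key in ("const", "noise_sd"):
                continue
            out += coef * (shocks[key] if key in shocks else upstream[key])
        return out + noise_rng.normal(0.0, eq["noise_sd"], size=n)

    x = equation(params.x_eq, r_x, {})
    bmi = equation(params.bmi_eq, r_bmi, {"x": x})
    log_crp = equation(params.crp_eq, r_crp, {"x": x})
    y = equation(params.y_eq, r_y, {"x": x, "bmi": bmi, "crp": log_crp})

    # keep generated values inside the data model's hard ranges; at the
    # default parameters this touches ~1e-4 of rows and is negligible for
    # the implied-path oracle
    bmi = np.clip(bmi, 10.01, 79.99)
    y = np.clip(y, 3298.13, None)

    cotinine = np.exp(x)
    below_lod = cotinine < params.lod_cotinine
    cotinine = np.where(below_lod, params.lod_cotinine, cotinine)
    crp = np.exp(log_crp)

    frame = pd.DataFrame({
        "age": age,
        "sex": np.where(female > 0, "female", "male"),
        "race": np.where(black > 0, "black", "white"),
        "physical_activity": np.asarray(ACTIVITY_LEVELS, dtype=object)[activity],
        "alcohol_use": np.asarray(ALCOHOL_LEVELS, dtype=object)[alcohol.astype(int)],
        "current_smoker": smoker > 0,
        "cotinine": cotinine,
        "cotinine_below_lod": below_lod,
        "crp": crp,
        "crp_below_lod": False,
        "bmi": bmi,
        "ltl_bp": y if params.ltl_output in ("bp", "both") else np.nan,
        "ts_ratio": bp_to_ts(y) if params.ltl_output in ("ts", "both") else np.nan,
    })
    return CohortTable(frame, provenance=f"synthetic seed={params.seed} n={n}")


def load_fixture_cohort() -> CohortTable:
    """Bundled n=500 fixture cohort (fixed seed) for fast tests."""
    from .datamodel import read_cohort

    path = Path(__file__).parent / "data" / "cohort_n500.csv"
    return read_cohort(path, provenance="bundled fixture (n=500)")
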