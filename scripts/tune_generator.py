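"""Tune the default synthetic-generator coefficients.

Solves for the structural slopes that make the analytic implied
standardized paths hit the reference magnitudes the default generator is
documented to reproduce (action paths, dual-model outcome coefficients and
the direct effect).  Prints the tuned equation dicts to paste into
``thirdvar.synthetic`` defaults.

Run from the repository root:  python scripts/tune_generator.py
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from thirdvar.synthetic import SyntheticParams, implied_standardized_paths

# target implied standardized coefficients
TARGETS = {
    "beta1_bmi": -0.079,
    "beta1_crp": 0.109,
    "c_prime": -0.045,
    "beta2_bmi": -0.036,
    "beta2_crp": -0.061,
    "age": -0.386,
    "black_race": 0.080,
    "female_sex": 0.062,
    "active_pa": 0.040,
    "alcohol_use": 0.038,
}

FREE = [
    ("bmi_eq", "x"),
    ("crp_eq", "x"),
    ("y_eq", "x"),
    ("y_eq", "bmi"),
    ("y_eq", "crp"),
    ("y_eq", "age"),
    ("y_eq", "black"),
    ("y_eq", "female"),
    ("y_eq", "active"),
    ("y_eq", "alcohol"),
]


def with_values(base: SyntheticParams, values) -> SyntheticParams:
    eqs = {n: dict(getattr(base, n)) for n in ("x_eq", "bmi_eq", "crp_eq", "y_eq")}
    for (eq, key), val in zip(FREE, values):
        eqs[eq][key] = float(val)
    return base.replace(**eqs)


def residuals(values, base: SyntheticParams) -> np.ndarray:
    params = with_values(base, values)
    imp = implied_standardized_paths(params)
    got = {
        "beta1_bmi": imp.beta1["bmi"],
        "beta1_crp": imp.beta1["crp"],
        "c_prime": imp.c_prime,
        "beta2_bmi": imp.beta2["bmi"],
        "beta2_crp": imp.beta2["crp"],
        "age": imp.outcome_betas["age"],
        "black_race": imp.outcome_betas["black_race"],
        "female_sex": imp.outcome_betas["female_sex"],
        "active_pa": imp.outcome_betas["active_pa"],
        "alcohol_use": imp.outcome_betas["alcohol_use"],
    }
    return np.array([got[k] - TARGETS[k] for k in TARGETS])


def main() -> None:
    base = SyntheticParams()
    x0 = [dict(getattr(base, eq))[key] for eq, key in FREE]
    sol = least_squares(residuals, x0, args=(base,), xtol=1e-14, ftol=1e-14)
    tuned = with_values(base, sol.x)
    imp = implied_standardized_paths(tuned)
    print("residual max |err| =", np.abs(sol.fun).max())
    print("implied: c=%.6f c'=%.6f" % (imp.c, imp.c_prime))
    print("beta1:", {k: round(v, 6) for k, v in imp.beta1.items()})
    print("beta2:", {k: round(v, 6) for k, v in imp.beta2.items()})
    print("outcome betas:", {k: round(v, 6) for k, v in imp.outcome_betas.items()})
    for eq in ("x_eq", "bmi_eq", "crp_eq", "y_eq"):
        print(f"{eq} =", {k: round(v, 6) for k, v in dict(getattr(tuned, eq)).items()})


if __name__ == "__main__":
    main()
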