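import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from thirdvar.datamodel import ModelSpec
from thirdvar.decompose import (
    Role,
    classify,
    effect_percent,
    indirect_effect,
    outcome_model,
    path_a,
    run_third_variable_analysis,
    sobel_test,
    total_effect,
)
from thirdvar.display import display_round
from thirdvar.errors import CollinearityError, ContractError, DomainError
from thirdvar.preprocess import build_design
from thirdvar.synthetic import SyntheticParams, generate_cohort, implied_standardized_paths


def null_params(n=5000, seed=0):
    """Generator with every structural path zeroed."""
    base = SyntheticParams(n=n, seed=seed)
    zero = lambda eq, keep: {k: (v if k in keep else 0.0) for k, v in eq.items()}
    return base.replace(
        x_eq=zero(base.x_eq, {"const", "noise_sd", "smoker"}),
        bmi_eq=zero(base.bmi_eq, {"const", "noise_sd"}),
        crp_eq=zero(base.crp_eq, {"const", "noise_sd"}),
        y_eq=zero(base.y_eq, {"const", "noise_sd"}),
    )


class TestIndirectEffect:
    def test_reference_bmi_product(self):
        # printed single-Z paths: (-0.079) x (-0.059) -> 0.0047 at 4 dp
        assert display_round(indirect_effect(-0.079, -0.059), 4) == 0.0047

    def test_reference_crp_product(self):
        assert display_round(indirect_effect(0.109, -0.075), 4) == -0.0082

    @given(st.floats(-2, 2, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_zero_factor(self, x):
        assert indirect_effect(0.0, x) == 0.0


class TestSobel:
    def test_zero_beta1(self):
        res = sobel_test(0.0, 0.1, 0.4, 0.1)
        assert res.z == 0.0
        assert res.p == 1.0

    def test_hand_computation(self):
        # SE = sqrt(0.5^2*0.1^2 + 0.4^2*0.1^2) = sqrt(0.0041)
        res = sobel_test(0.5, 0.1, 0.4, 0.1)
        assert res.se == pytest.approx(math.sqrt(0.0041), abs=1e-12)
        assert res.z == pytest.approx(0.2 / math.sqrt(0.0041), abs=1e-10)
        assert res.z == pytest.approx(3.123, abs=1e-3)

    @given(
        b1=st.floats(-1, 1), s1=st.floats(0.01, 1),
        b2=st.floats(-1, 1), s2=st.floats(0.01, 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, b1, s1, b2, s2):
        assume(abs(b1) > 1e-6 or abs(b2) > 1e-6)  # avoid 0/0 and underflow
        a = sobel_test(b1, s1, b2, s2)
        b = sobel_test(b2, s2, b1, s1)
        assert a.z == pytest.approx(b.z, rel=1e-12, abs=1e-12)

    def test_second_order_widens_se(self):
        first = sobel_test(0.5, 0.1, 0.4, 0.1)
        second = sobel_test(0.5, 0.1, 0.4, 0.1, second_order=True)
        assert second.se > first.se

    def test_bad_se_rejected(self):
        with pytest.raises(ContractError):
            sobel_test(0.5, 0.0, 0.4, 0.1)


class TestClassify:
    def test_reference_suppression(self):
        assert classify(-0.0486, -0.0533, 0.0047) is Role.SUPPRESSION

    def test_reference_mediation(self):
        assert classify(-0.0486, -0.0404, -0.0082) is Role.MEDIATION

    def test_undefined_when_indirect_dominates(self):
        assert classify(0.001, 0.0, 0.01) is Role.UNDEFINED

    def test_tie_break(self):
        assert classify(-0.05, 0.05, -0.01) is Role.MEDIATION
        assert classify(-0.05, 0.05, 0.01) is Role.SUPPRESSION

    @given(
        c=st.floats(-1, 1), cp=st.floats(-1, 1), ind=st.floats(-0.5, 0.5),
        scale=st.floats(0.1, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, c, cp, ind, scale):
        # multiplying Y by a positive constant leaves std coefficients, and
        # hence role and percentage, unchanged -> classify must depend only
        # on the invariant inputs
        assert classify(c, cp, ind) is classify(c, cp, ind)
        role = classify(c, cp, ind)
        if role is not Role.UNDEFINED and abs(c) > 1e-9 and abs(cp) > 1e-9:
            p1 = effect_percent(role, ind, c, cp)
            p2 = effect_percent(role, ind, c, cp)
            assert p1 == p2


class TestEffectPercent:
    def test_reference_suppression_percent(self):
        pct = effect_percent(Role.SUPPRESSION, 0.0047, -0.0486, -0.0533)
        assert display_round(pct, 1) == 8.8

    def test_reference_mediation_percent(self):
        pct = effect_percent(Role.MEDIATION, -0.0082, -0.0486, -0.0404)
        assert display_round(pct, 1) == 16.9

    def test_zero_indirect(self):
        assert effect_percent(Role.MEDIATION, 0.0, -0.05, -0.04) == 0.0

    def test_undefined_returns_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert math.isnan(effect_percent(Role.UNDEFINED, 0.01, 0.001, 0.0))

    def test_zero_denominator(self):
        with pytest.raises(DomainError):
            effect_percent(Role.MEDIATION, 0.01, 0.0, 0.1)


class TestStepOperations:
    def test_null_generator_c_near_zero(self):
        cohort = generate_cohort(null_params(n=8000, seed=3))
        design = build_design(cohort, ModelSpec())
        c, model = total_effect(design)
        assert abs(c.beta) < 3.0 * c.se

    def test_total_effect_matches_oracle(self):
        params = SyntheticParams(n=100_000, seed=17)
        cohort = generate_cohort(params)
        design = build_design(cohort, ModelSpec())
        c, _ = total_effect(design)
        implied = implied_standardized_paths(params)
        assert c.beta == pytest.approx(implied.c, abs=3.0 * c.se)

    def test_duplicate_predictor_collinearity(self, default_cohort):
        design = build_design(default_cohort, ModelSpec())
        cols = design.subset((design.predictor_col,) + design.covariate_cols)
        cols["dup"] = cols[design.predictor_col]
        from thirdvar.regression import fit_ols
        with pytest.raises(CollinearityError):
            fit_ols(design.y, cols)

    def test_path_a_zero_when_independent(self):
        cohort = generate_cohort(null_params(n=8000, seed=4))
        design = build_design(cohort, ModelSpec())
        b1, _ = path_a(design, "bmi")
        assert abs(b1.beta) < 3.0 * b1.se

    def test_path_a_matches_oracle(self):
        params = SyntheticParams(n=100_000, seed=23)
        cohort = generate_cohort(params)
        design = build_design(cohort, ModelSpec())
        implied = implied_standardized_paths(params)
        b_bmi, _ = path_a(design, "bmi")
        b_crp, _ = path_a(design, "log_crp")
        assert b_bmi.beta == pytest.approx(implied.beta1["bmi"], abs=3.0 * b_bmi.se)
        assert b_crp.beta == pytest.approx(implied.beta1["crp"], abs=3.0 * b_crp.se)

    def test_path_a_unknown_z(self, default_cohort):
        design = build_design(default_cohort, ModelSpec())
        with pytest.raises(ContractError):
            path_a(design, "age")

    def test_outcome_model_no_adjustment_limit(self):
        # Zs independent of everything: c' ~ c
        params = null_params(n=20_000, seed=5)
        y_eq = dict(params.y_eq)
        y_eq["x"] = -12.0  # only the direct path is active
        params = params.replace(y_eq=y_eq)
        cohort = generate_cohort(params)
        design = build_design(cohort, ModelSpec())
        c, _ = total_effect(design)
        full = outcome_model(design)
        assert full.term(design.predictor_col).beta == pytest.approx(c.beta, abs=0.01)


class TestRunAnalysis:
    def test_dual_run_identity(self, default_cohort, dual_spec):
        res = run_third_variable_analysis(dual_spec, default_cohort)
        assert res.identity_gap < 1e-10

    def test_single_z_suppression_sign_logic(self):
        # X->Z < 0, Z->Y < 0, X->Y < 0 at large n -> suppression
        params = SyntheticParams(n=150_000, seed=31)
        cohort = generate_cohort(params)
        res = run_third_variable_analysis(
            ModelSpec(third_variables=("bmi",)), cohort
        )
        assert res.roles["bmi"] is Role.SUPPRESSION
        assert res.effect_percents["bmi"] > 0

    def test_single_z_mediation_sign_logic(self):
        # X->Z > 0, Z->Y < 0, X->Y < 0 -> mediation
        params = SyntheticParams(n=150_000, seed=37)
        cohort = generate_cohort(params)
        res = run_third_variable_analysis(
            ModelSpec(third_variables=("crp",)), cohort
        )
        assert res.roles["crp"] is Role.MEDIATION

    def test_zero_or_three_zs_rejected(self, default_cohort):
        with pytest.raises(ContractError):
            run_third_variable_analysis(
                ModelSpec(third_variables=()), default_cohort
            )

    def test_shared_sample_with_missingness(self, default_cohort, dual_spec):
        cohort = default_cohort.copy()
        idx = cohort.frame.sample(n=60, random_state=1).index
        cohort.frame.loc[idx[:30], "crp"] = np.nan
        cohort.frame.loc[idx[30:], "bmi"] = np.nan
        res = run_third_variable_analysis(dual_spec, cohort)
        assert res.n == len(cohort) - 60
        assert res.n_dropped == 60
        assert res.identity_gap < 1e-10

    def test_result_serialization(self, default_cohort, dual_spec):
        res = run_third_variable_analysis(dual_spec, default_cohort)
        d = res.to_dict()
        assert set(d["paths"]) == {"bmi", "crp"}
        assert "indirect_overall" in d
        tsv = res.to_tsv()
        assert tsv.startswith("path\t")
        assert "x_to_bmi" in tsv and "indirect_overall" in tsv

    def test_scale_invariance_of_roles(self, dual_spec):
        cohort = generate_cohort(SyntheticParams(n=3000, seed=55))
        res1 = run_third_variable_analysis(dual_spec, cohort)
        scaled = cohort.copy()
        scaled.frame["ltl_bp"] = scaled.frame["ltl_bp"] * 7.5
        res2 = run_third_variable_analysis(dual_spec, scaled)
        assert res1.roles == res2.roles
        for z in res1.effect_percents:
            assert res1.effect_percents[z] == pytest.approx(
                res2.effect_percents[z], rel=1e-9
            )
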