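import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from thirdvar.errors import CollinearityError, ContractError, DegenerateTableError
from thirdvar.preprocess import standardize
from thirdvar.regression import (
    INTERCEPT,
    adjusted_means,
    chi_square_test,
    fit_ols,
    standardized_betas,
)


def normal_equations(y, X):
    """Independent oracle: explicit normal-equations solve with intercept."""
    A = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(A.T @ A, A.T @ y)


class TestFitOls:
    def test_identity_fit(self):
        x = np.arange(10, dtype=float)
        fit = fit_ols(x, {"x": x})
        assert fit.params["x"] == pytest.approx(1.0, abs=1e-12)
        assert fit.params[INTERCEPT] == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_intercept_only(self):
        y = np.array([2.0, 4.0, 9.0, 1.0])
        fit = fit_ols(y, {})
        assert fit.params[INTERCEPT] == pytest.approx(y.mean())

    def test_five_point_normal_equations(self):
        # y = 2x + 1 with fixed perturbations
        x = np.arange(1.0, 6.0)
        y = 2.0 * x + 1.0 + np.array([0.1, -0.2, 0.05, 0.3, -0.25])
        expected = normal_equations(y, x[:, None])
        fit = fit_ols(y, {"x": x})
        assert fit.params[INTERCEPT] == pytest.approx(expected[0], abs=1e-10)
        assert fit.params["x"] == pytest.approx(expected[1], abs=1e-10)

    @given(st.integers(0, 5_000))
    @settings(max_examples=40, deadline=None)
    def test_random_small_designs_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        k = int(rng.integers(1, 4))
        X = rng.normal(size=(n, k))
        y = rng.normal(size=n)
        expected = normal_equations(y, X)
        fit = fit_ols(y, {f"x{j}": X[:, j] for j in range(k)})
        got = [fit.params[INTERCEPT]] + [fit.params[f"x{j}"] for j in range(k)]
        assert np.allclose(got, expected, atol=1e-8)

    def test_duplicated_column_collinearity(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        with pytest.raises(CollinearityError) as err:
            fit_ols(y, {"a": x, "b": 2.0 * x})
        assert err.value.column == "b"

    def test_too_few_rows(self, rng):
        with pytest.raises(ContractError):
            fit_ols(rng.normal(size=3), {"a": rng.normal(size=3), "b": rng.normal(size=3)})


class TestStandardizedBetas:
    def test_simple_regression_equals_correlation(self, rng):
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        fit = fit_ols(y, {"x": x})
        scaling = {"x": standardize(x)[1], "y": standardize(y)[1]}
        res = standardized_betas(fit, scaling, "y")
        r = np.corrcoef(x, y)[0, 1]
        assert res.term("x").beta == pytest.approx(r, abs=1e-12)

    def test_prestandardized_equals_raw(self, rng):
        x = standardize(rng.normal(size=100))[0]
        y = standardize(0.3 * x + rng.normal(size=100))[0]
        fit = fit_ols(y, {"x": x})
        scaling = {"x": standardize(x)[1], "y": standardize(y)[1]}
        res = standardized_betas(fit, scaling, "y")
        assert res.term("x").beta == pytest.approx(fit.params["x"], abs=1e-12)

    def test_matches_refit_on_zscored(self, rng):
        n, k = 300, 4
        X = rng.normal(size=(n, k)) @ (np.eye(k) + 0.3)
        y = X @ np.array([0.5, -0.2, 0.1, 0.0]) + rng.normal(size=n)
        cols = {f"x{j}": X[:, j] for j in range(k)}
        fit = fit_ols(y, cols)
        scaling = {name: standardize(col)[1] for name, col in cols.items()}
        scaling["y"] = standardize(y)[1]
        res = standardized_betas(fit, scaling, "y")
        zcols = {name: standardize(col)[0] for name, col in cols.items()}
        zfit = fit_ols(standardize(y)[0], zcols)
        for name in cols:
            assert res.term(name).beta == pytest.approx(zfit.params[name], abs=1e-10)

    def test_p_values_unchanged(self, rng):
        x = rng.normal(size=80)
        y = 0.4 * x + rng.normal(size=80)
        fit = fit_ols(y, {"x": x})
        scaling = {"x": standardize(x)[1], "y": standardize(y)[1]}
        res = standardized_betas(fit, scaling, "y")
        assert res.term("x").p == fit.p["x"]

    def test_ci_p_coherence(self, rng):
        # p < 0.05 iff the 95% CI excludes zero, for every term
        for _ in range(10):
            n = 60
            X = rng.normal(size=(n, 3))
            y = X @ rng.normal(scale=0.2, size=3) + rng.normal(size=n)
            cols = {f"x{j}": X[:, j] for j in range(3)}
            fit = fit_ols(y, cols)
            scaling = {name: standardize(col)[1] for name, col in cols.items()}
            scaling["y"] = standardize(y)[1]
            res = standardized_betas(fit, scaling, "y")
            for t in res.terms:
                excludes = t.ci_low > 0 or t.ci_high < 0
                assert (t.p < 0.05) == excludes
                assert t.ci_low <= t.beta <= t.ci_high

    def test_missing_scaling_contract_error(self, rng):
        x = rng.normal(size=50)
        fit = fit_ols(rng.normal(size=50), {"x": x})
        with pytest.raises(ContractError):
            standardized_betas(fit, {"x": standardize(x)[1]}, "y")


class TestAdjustedMeans:
    def test_null_adjuster_gives_raw_means(self, rng):
        g = np.repeat(["a", "b"], 40)
        y = np.where(g == "a", 1.0, 3.0) + rng.normal(size=80) * 0.1
        adj = rng.normal(size=80)  # uncorrelated with group and outcome
        res = adjusted_means(y, g, adj)
        assert res.means["a"] == pytest.approx(y[g == "a"].mean(), abs=0.05)
        assert res.means["b"] == pytest.approx(y[g == "b"].mean(), abs=0.05)

    def test_identical_groups(self, rng):
        y = np.tile(rng.normal(size=30), 2)
        g = np.repeat(["a", "b"], 30)
        adj = np.tile(rng.normal(size=30), 2)
        res = adjusted_means(y, g, adj)
        assert res.means["a"] == pytest.approx(res.means["b"], abs=1e-10)
        assert res.p == pytest.approx(1.0, abs=1e-10)

    def test_recovers_group_effect_under_confounding(self, rng):
        # age confounds: group b is older and age lowers y
        n = 4000
        g = np.repeat(["a", "b"], n // 2)
        age = np.where(g == "a", 40.0, 55.0) + rng.normal(size=n, scale=8.0)
        y = 100.0 + np.where(g == "a", 0.0, 5.0) - 1.0 * age + rng.normal(size=n, scale=3.0)
        res = adjusted_means(y, g, age)
        assert res.means["b"] - res.means["a"] == pytest.approx(5.0, abs=0.5)
        # raw means are dominated by the age gap, not the group effect
        raw_diff = y[g == "b"].mean() - y[g == "a"].mean()
        assert raw_diff < 0

    def test_single_group_rejected(self, rng):
        with pytest.raises(ContractError):
            adjusted_means(rng.normal(size=10), np.repeat("a", 10), rng.normal(size=10))


class TestChiSquare:
    def test_proportional_table(self):
        res = chi_square_test([[10, 20], [30, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_textbook_formula_on_reference_counts(self):
        # 2x2 smoker-by-sex table: 416 of 1630 males, 364 of 1484 females
        table = np.array([[416.0, 1630.0 - 416.0], [364.0, 1484.0 - 364.0]])
        # independent oracle: explicit Pearson formula
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        stat_oracle = ((table - expected) ** 2 / expected).sum()
        res = chi_square_test(table)
        assert res.statistic == pytest.approx(stat_oracle, rel=1e-12)
        assert res.df == 1

    def test_zero_row_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi_square_test([[0, 0], [5, 10]])

    def test_df_formula(self):
        res = chi_square_test([[5, 6, 7], [8, 9, 10]])
        assert res.df == 2
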