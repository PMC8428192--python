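import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fraghr import (
    CohortSimParams,
    ModelSpec,
    fit_change_model,
    fit_model,
    likelihood_ratio_test,
    quadratic_age_trend,
    quartile_table,
    simulate_cohort,
    standardize,
    transform_variables,
)
from fraghr.cohort import two_group_compare


@pytest.fixture
def cohort500():
    df = simulate_cohort(CohortSimParams(n_subjects=500, seed=11))
    df["education"] = df["education"].astype(float)
    return df


class TestTransforms:
    def test_zero_inflated_gets_offset_log(self):
        df = pd.DataFrame({"pack_years": [0.0, np.e - 1.0]})
        out, reg = transform_variables(df)
        assert out["pack_years"].tolist() == pytest.approx([0.0, 1.0])
        assert reg["pack_years"] == "ln1p"

    def test_plain_log_without_offset(self):
        df = pd.DataFrame({"nt_probnp": [67.53], "rmssd": [28.6]})
        out, reg = transform_variables(df)
        assert out["nt_probnp"].iloc[0] == pytest.approx(4.2126, abs=1e-4)
        assert out["rmssd"].iloc[0] == pytest.approx(3.3534, abs=1e-4)
        assert reg == {"rmssd": "ln", "nt_probnp": "ln"}

    def test_negative_value_raises_with_context(self):
        df = pd.DataFrame({"hf": [10.0, -1.0]})
        with pytest.raises(ValueError, match="hf"):
            transform_variables(df)

    def test_untouched_columns_pass_through(self):
        df = pd.DataFrame({"age": [60.0], "rmssd": [30.0]})
        out, _ = transform_variables(df)
        assert out["age"].iloc[0] == 60.0


class TestStandardize:
    def test_mean_zero_sd_one(self, cohort500):
        out, reg = standardize(cohort500, ["age", "pnnss"])
        assert abs(out["age"].mean()) < 1e-12
        assert out["age"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert set(reg["variable"]) == {"age", "pnnss"}

    def test_coefficient_scales_by_sd(self, cohort500):
        raw = fit_model(
            cohort500, ModelSpec(1, "score_exam1", "pnnss", covariates=())
        )
        std, reg = standardize(cohort500, ["pnnss"])
        scaled = fit_model(
            std, ModelSpec(1, "score_exam1", "pnnss", covariates=())
        )
        sd = float(reg.loc[0, "sd"])
        assert scaled.coef("pnnss") == pytest.approx(raw.coef("pnnss") * sd)

    def test_outcome_left_unstandardized(self, cohort500):
        out, _ = standardize(cohort500, ["age"])
        assert out["score_exam1"].equals(cohort500["score_exam1"])

    def test_zero_sd_rejected(self):
        df = pd.DataFrame({"x": [1.0] * 20})
        with pytest.raises(ValueError, match="SD"):
            standardize(df, ["x"])


class TestFitModel:
    def test_exact_linear_relationship(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "y": 3.0 + 2.0 * x})
        fit = fit_model(df, ModelSpec(1, "y", "x", covariates=()))
        assert fit.coef("x") == pytest.approx(2.0, abs=1e-10)
        assert fit.coef("const") == pytest.approx(3.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_intercept_only_recovers_mean(self, cohort500):
        fit = fit_model(cohort500, ModelSpec(1, "score_exam1", "", covariates=()))
        assert fit.coef("const") == pytest.approx(cohort500["score_exam1"].mean())

    def test_matches_normal_equations_oracle(self, cohort500):
        rng = np.random.default_rng(3)
        n, p = 150, 6
        X = rng.normal(size=(n, p))
        beta = rng.normal(size=p)
        y = X @ beta + rng.normal(scale=0.5, size=n)
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
        df["y"] = y
        fit = fit_model(
            df, ModelSpec(1, "y", "x0", covariates=tuple(f"x{i}" for i in range(1, p)))
        )
        Xd = np.column_stack([np.ones(n), X])
        oracle = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        got = np.array([fit.coef("const")] + [fit.coef(f"x{i}") for i in range(p)])
        assert np.allclose(got, oracle, rtol=1e-8)

    def test_rank_deficient_design_rejected(self, cohort500):
        df = cohort500.assign(age_copy=cohort500["age"])
        with pytest.raises(ValueError, match="collinear|rank"):
            fit_model(df, ModelSpec(1, "score_exam1", "age",
                                    covariates=("age_copy",)))

    def test_complete_case_rows(self, cohort500):
        df = cohort500.copy()
        df.loc[:49, "pnnss"] = np.nan
        fit = fit_model(df, ModelSpec(1, "score_exam1", "pnnss", covariates=()))
        assert fit.n == 450

    def test_ci_brackets_estimate(self, cohort500):
        fit = fit_model(cohort500, ModelSpec(1, "score_exam1", "pnnss", covariates=()))
        lo, hi = fit.ci("pnnss")
        assert lo < fit.coef("pnnss") < hi
        assert fit.adj_r_squared <= fit.r_squared


class TestChangeModel:
    def test_equivalence_with_followup_regression(self, cohort500):
        covs = ("age", "male", "education")
        d = fit_change_model(
            cohort500,
            ModelSpec(3, "score_exam2", "pnnss", covariates=covs, change_score=True),
        )
        y2 = fit_model(
            cohort500,
            ModelSpec(3, "score_exam2", "pnnss", covariates=("score_exam1",) + covs),
        )
        td = d.terms.set_index("term")["estimate"]
        t2 = y2.terms.set_index("term")["estimate"]
        for term in ("pnnss", "age", "male", "education", "const"):
            assert td[term] == pytest.approx(t2[term], abs=1e-10)
        assert td["score_exam1"] - t2["score_exam1"] == pytest.approx(-1.0, abs=1e-10)

    def test_null_change_effect_not_detected(self):
        params = CohortSimParams(n_subjects=1500, seed=21, change_beta_pnnss=0.0)
        df = simulate_cohort(params)
        df["education"] = df["education"].astype(float)
        fit = fit_change_model(
            df, ModelSpec(3, "score_exam2", "pnnss", covariates=("age",),
                          change_score=True)
        )
        lo, hi = fit.ci("pnnss")
        z = fit.coef("pnnss") / ((hi - lo) / (2 * 1.96))
        assert abs(z) < 3.0

    def test_structural_change_coefficient_recovered(self):
        df = simulate_cohort(CohortSimParams(n_subjects=1000, seed=22))
        df, _ = standardize(df, ["age", "pnnss"])
        fit = fit_change_model(
            df, ModelSpec(3, "score_exam2", "pnnss", covariates=("age",),
                          change_score=True)
        )
        lo, hi = fit.ci("pnnss")
        assert lo <= -0.44 <= hi


class TestLRT:
    def test_identical_models_give_zero(self, cohort500):
        fit = fit_model(cohort500, ModelSpec(1, "score_exam1", "pnnss", covariates=()))
        res = likelihood_ratio_test(fit, fit)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_statistic_matches_rss_identity(self, cohort500):
        base = fit_model(cohort500, ModelSpec(1, "score_exam1", "pnnss", covariates=()))
        ext = fit_model(
            cohort500, ModelSpec(1, "score_exam1", "pnnss", covariates=("age", "male"))
        )
        res = likelihood_ratio_test(base, ext)
        expected = base.n * np.log(base.rss / ext.rss)
        assert res.statistic == pytest.approx(expected, rel=1e-10)
        assert res.df == 2

    def test_non_nested_rejected(self, cohort500):
        a = fit_model(cohort500, ModelSpec(1, "score_exam1", "age", covariates=()))
        b = fit_model(cohort500, ModelSpec(1, "score_exam1", "pnnss", covariates=()))
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(a, b)

    def test_different_rows_rejected(self, cohort500):
        a = fit_model(cohort500, ModelSpec(1, "score_exam1", "pnnss", covariates=()))
        b = fit_model(
            cohort500.iloc[:400], ModelSpec(1, "score_exam1", "pnnss", covariates=("age",))
        )
        with pytest.raises(ValueError, match="rows"):
            likelihood_ratio_test(a, b)

    def test_power_against_strong_effect(self):
        """Adding a covariate with a true effect of half the residual SD per
        SD is detected essentially always at n=500."""
        rng = np.random.default_rng(31)
        rejections = 0
        for r in range(50):
            n = 500
            x = rng.normal(size=n)
            w = rng.normal(size=n)
            y = 1.0 + 0.5 * 2.0 * w + rng.normal(scale=2.0, size=n)
            df = pd.DataFrame({"x": x, "w": w, "y": y})
            base = fit_model(df, ModelSpec(1, "y", "x", covariates=()))
            ext = fit_model(df, ModelSpec(1, "y", "x", covariates=("w",)))
            rejections += likelihood_ratio_test(base, ext).p_value < 0.05
        assert rejections >= 48


class TestQuadraticAgeTrend:
    def test_exact_parabola_recovered(self):
        age = np.linspace(50, 90, 60)
        df = pd.DataFrame({"age": age, "m": 2.0 - 0.3 * age + 0.01 * age**2})
        res = quadratic_age_trend(df, "m")
        assert res["coefficients"]["age2"] == pytest.approx(0.01, abs=1e-10)
        assert np.allclose(res["band_high"] - res["band_low"], 0.0, atol=1e-6)

    def test_linear_trend_has_no_quadratic_term(self):
        rng = np.random.default_rng(5)
        hits = 0
        for r in range(20):
            age = rng.uniform(55, 85, 300)
            df = pd.DataFrame({"age": age, "m": 50 + 0.5 * age + rng.normal(0, 3, 300)})
            res = quadratic_age_trend(df, "m")
            hits += res["p_values"]["age2"] >= 0.05
        assert hits >= 18

    def test_u_shape_detected(self):
        rng = np.random.default_rng(6)
        hits = 0
        for r in range(20):
            age = rng.uniform(55, 85, 300)
            m = 30 + 0.05 * (age - 70) ** 2 + rng.normal(0, 2, 300)
            res = quadratic_age_trend(pd.DataFrame({"age": age, "m": m}), "m")
            hits += (res["coefficients"]["age2"] > 0) and (res["p_values"]["age2"] < 0.05)
        assert hits >= 18

    def test_small_sample_rejected(self):
        df = pd.DataFrame({"age": np.arange(5.0), "m": np.arange(5.0)})
        with pytest.raises(ValueError, match="10"):
            quadratic_age_trend(df, "m")


class TestQuartileTable:
    def test_quartile_sizes_balanced_without_ties(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"pnnss": rng.normal(size=101), "age": rng.normal(size=101)})
        tab = quartile_table(df, "pnnss", continuous=["age"])
        sizes = []
        from fraghr.cohort import _quartile_assign
        q = _quartile_assign(df["pnnss"].to_numpy())
        for k in range(4):
            sizes.append(int((q == k).sum()))
        assert max(sizes) - min(sizes) <= 1

    def test_reports_anova_and_chi2(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "pnnss": rng.normal(66, 13, 400),
                "age": rng.normal(68, 9, 400),
                "male": rng.integers(0, 2, 400),
            }
        )
        tab = quartile_table(df, "pnnss", continuous=["age"], categorical=["male"])
        assert set(tab["test"]) == {"anova", "chi2"}
        assert tab["p_value"].notna().all()

    def test_anova_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(9)
        pvals = []
        for r in range(200):
            df = pd.DataFrame(
                {"pnnss": rng.normal(size=80), "age": rng.normal(size=80)}
            )
            tab = quartile_table(df, "pnnss", continuous=["age"])
            pvals.append(float(tab["p_value"].iloc[0]))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_two_group_comparison(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {
                "group": np.repeat([0, 1], 100),
                "value": np.concatenate(
                    [rng.normal(0, 1, 100), rng.normal(2, 1, 100)]
                ),
            }
        )
        assert two_group_compare(df, "group", "value") < 1e-6
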