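"""Design construction, WLS, and modified-Poisson fitters against oracles."""

import numpy as np
import pandas as pd
import pytest

from tweethood.models import (
    ModelError,
    ModelSpec,
    build_design,
    fit_modified_poisson,
    fit_weighted_linear,
)


def design_2x2(a, b, c, d):
    """Exposed: a cases / a+b total; unexposed: c cases / c+d total."""
    n1, n0 = a + b, c + d
    X = pd.DataFrame(
        {"intercept": np.ones(n1 + n0), "exposed": np.r_[np.ones(n1), np.zeros(n0)]}
    )
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return X, y, np.ones(n1 + n0)


class TestModifiedPoisson:
    def test_two_by_two_matches_closed_form_prevalence_ratio(self):
        X, y, w = design_2x2(10, 90, 20, 80)
        fit = fit_modified_poisson(X, y, w, terms=["exposed"])[0]
        assert fit.estimate == pytest.approx((10 / 100) / (20 / 100), abs=1e-6)

    def test_weighted_two_by_two_matches_weighted_prevalence_ratio(self):
        X, y, _ = design_2x2(10, 90, 20, 80)
        rng = np.random.default_rng(0)
        w = rng.lognormal(0, 0.5, len(y))
        exposed = X["exposed"].to_numpy() == 1
        p1 = np.average(y[exposed], weights=w[exposed])
        p0 = np.average(y[~exposed], weights=w[~exposed])
        fit = fit_modified_poisson(X, y, w, terms=["exposed"])[0]
        assert fit.estimate == pytest.approx(p1 / p0, abs=1e-6)

    def test_null_association_gives_pr_near_one(self):
        rng = np.random.default_rng(1)
        n = 20000
        X = pd.DataFrame({"intercept": np.ones(n), "exposed": rng.integers(0, 2, n).astype(float)})
        y = (rng.random(n) < 0.3).astype(float)
        fit = fit_modified_poisson(X, y, np.ones(n), terms=["exposed"])[0]
        assert fit.estimate == pytest.approx(1.0, abs=0.05)
        assert fit.ci_low < 1.0 < fit.ci_high

    def test_integer_weights_equal_duplicated_rows(self):
        X, y, _ = design_2x2(5, 15, 8, 12)
        w = np.tile([1.0, 2.0], 20)
        Xd = pd.DataFrame(np.repeat(X.to_numpy(), w.astype(int), axis=0), columns=X.columns)
        yd = np.repeat(y, w.astype(int))
        a = fit_modified_poisson(X, y, w)
        b = fit_modified_poisson(Xd, yd, np.ones(len(yd)))
        for fa, fb in zip(a, b):
            assert fa.estimate == pytest.approx(fb.estimate, abs=1e-8)

    def test_agrees_with_statsmodels_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        n = 500
        X = pd.DataFrame(
            {"intercept": np.ones(n), "x1": rng.normal(size=n), "x2": rng.integers(0, 2, n).astype(float)}
        )
        p = 0.25 * np.exp(0.2 * X["x1"].to_numpy() - 0.3 * X["x2"].to_numpy())
        y = (rng.random(n) < p).astype(float)
        w = rng.lognormal(0, 0.3, n)
        mine = fit_modified_poisson(X, y, w)
        # var_weights matches the survey-weight score convention w*(y-mu)*x
        glm = sm.GLM(y, X, family=sm.families.Poisson(), var_weights=w).fit(cov_type="HC0")
        np.testing.assert_allclose(
            [np.log(f.estimate) for f in mine], glm.params.to_numpy(), atol=1e-6
        )
        np.testing.assert_allclose([f.robust_se for f in mine], glm.bse.to_numpy(), rtol=1e-4)

    def test_robust_se_smaller_than_model_based_for_binary_outcome(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        n = 2000
        X = pd.DataFrame({"intercept": np.ones(n), "x": rng.integers(0, 2, n).astype(float)})
        y = (rng.random(n) < 0.4).astype(float)
        mine = fit_modified_poisson(X, y, np.ones(n))
        naive = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.mean([f.robust_se for f in mine]) < np.mean(naive.bse.to_numpy())

    def test_rejects_nonbinary_outcome(self):
        X = pd.DataFrame({"intercept": np.ones(4)})
        with pytest.raises(ValueError, match="binary"):
            fit_modified_poisson(X, np.array([0.0, 1.0, 2.0, 0.0]), np.ones(4))

    def test_pr_ci_is_multiplicative_and_contains_estimate(self):
        X, y, w = design_2x2(30, 70, 50, 50)
        fit = fit_modified_poisson(X, y, w, terms=["exposed"])[0]
        assert fit.ci_low <= fit.estimate <= fit.ci_high
        # symmetric on the log scale
        assert np.log(fit.estimate) - np.log(fit.ci_low) == pytest.approx(
            np.log(fit.ci_high) - np.log(fit.estimate), abs=1e-10
        )


class TestWeightedLinear:
    def test_binary_predictor_equals_difference_of_group_means(self):
        rng = np.random.default_rng(4)
        n = 200
        g = rng.integers(0, 2, n).astype(float)
        y = 1.5 + 2.0 * g + rng.normal(0, 1, n)
        X = pd.DataFrame({"intercept": np.ones(n), "g": g})
        fit = fit_weighted_linear(X, y, np.ones(n), terms=["g"])[0]
        assert fit.estimate == pytest.approx(y[g == 1].mean() - y[g == 0].mean(), abs=1e-10)

    def test_exact_linear_outcome_recovered_with_zero_se(self):
        X = pd.DataFrame({"intercept": np.ones(10), "x": np.arange(10.0)})
        y = 3.0 - 0.5 * np.arange(10.0)
        fits = fit_weighted_linear(X, y, np.ones(10))
        assert fits[0].estimate == pytest.approx(3.0, abs=1e-10)
        assert fits[1].estimate == pytest.approx(-0.5, abs=1e-10)
        assert fits[1].robust_se == pytest.approx(0.0, abs=1e-8)

    def test_weight_rescaling_leaves_estimates_unchanged(self):
        rng = np.random.default_rng(5)
        n = 100
        X = pd.DataFrame({"intercept": np.ones(n), "x": rng.normal(size=n)})
        y = rng.normal(size=n)
        w = rng.lognormal(0, 0.4, n)
        a = fit_weighted_linear(X, y, w)
        b = fit_weighted_linear(X, y, 2.0 * w)
        for fa, fb in zip(a, b):
            assert fa.estimate == pytest.approx(fb.estimate, abs=1e-12)

    def test_agrees_with_statsmodels_wls(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(6)
        n = 300
        X = pd.DataFrame({"intercept": np.ones(n), "x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        y = 1.0 + 0.5 * X["x1"].to_numpy() + rng.normal(0, 2, n)
        w = rng.lognormal(0, 0.3, n)
        mine = fit_weighted_linear(X, y, w)
        wls = sm.WLS(y, X, weights=w).fit(cov_type="HC0")
        np.testing.assert_allclose([f.estimate for f in mine], wls.params.to_numpy(), atol=1e-8)
        np.testing.assert_allclose([f.robust_se for f in mine], wls.bse.to_numpy(), rtol=1e-6)

    def test_rank_deficiency_names_collinear_column(self):
        X = pd.DataFrame({"intercept": np.ones(20), "a": np.arange(20.0), "b": 2 * np.arange(20.0)})
        with pytest.raises(ModelError, match="collinear"):
            fit_weighted_linear(X, np.zeros(20), np.ones(20))


class TestBuildDesign:
    @staticmethod
    def frame(n=9):
        rng = np.random.default_rng(7)
        return pd.DataFrame(
            {
                "bmi": rng.normal(29, 5, n),
                "tertile_happy": [1, 2, 3] * (n // 3),
                "exam_weight": np.ones(n),
                "age": rng.uniform(20, 80, n),
                "sex": ["female", "male", "female"] * (n // 3),
                "race_ethnicity": ["white", "black", "hispanic"] * (n // 3),
                "income_band": ["b1", "b3", "b5"] * (n // 3),
                "pct_nonhispanic_white_masked": rng.uniform(20, 90, n),
                "median_income_masked": rng.uniform(10, 12, n),
                "population_density_masked": rng.uniform(100, 5000, n),
                "median_age_masked": rng.uniform(25, 60, n),
            }
        )

    def test_tertile_dummy_coding_against_reference(self):
        df = self.frame()
        X, y, w = build_design(df, ModelSpec(outcome="bmi", characteristic="happy"))
        np.testing.assert_array_equal(X["happy_t2"].to_numpy()[:3], [0, 1, 0])
        np.testing.assert_array_equal(X["happy_t3"].to_numpy()[:3], [0, 0, 1])
        assert (X["intercept"] == 1.0).all()
        assert len(y) == len(w) == len(df)

    def test_dummy_partition_identity(self):
        df = self.frame()
        X, _, _ = build_design(df, ModelSpec(outcome="bmi", characteristic="happy"))
        race_cols = [c for c in X.columns if c.startswith("race_ethnicity_")]
        ref = 1.0 - X[race_cols].sum(axis=1)  # reference level indicator
        assert set(np.unique(X[race_cols].to_numpy())) <= {0.0, 1.0}
        assert ((ref == 1.0) | (X[race_cols].sum(axis=1) == 1.0)).all()

    def test_listwise_deletion_decrements_n(self):
        df = self.frame()
        df.loc[0, "age"] = np.nan
        X, y, _ = build_design(df, ModelSpec(outcome="bmi", characteristic="happy"))
        assert len(y) == len(df) - 1

    def test_empty_after_deletion_raises(self):
        df = self.frame()
        df["age"] = np.nan
        with pytest.raises(ModelError, match="no records"):
            build_design(df, ModelSpec(outcome="bmi", characteristic="happy"))

    def test_constant_column_raises(self):
        df = self.frame()
        df["tertile_happy"] = 2
        with pytest.raises(ModelError, match="constant"):
            build_design(df, ModelSpec(outcome="bmi", characteristic="happy"))
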