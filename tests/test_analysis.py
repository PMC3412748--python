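"""Statistical pipeline: dichotomization, screening, imputation, stepwise."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit

from ptssrisk.analysis import (
    c_statistic,
    dichotomize,
    em_impute,
    fit_adjusted,
    fit_logistic,
    screen_predictors,
    stepwise_logistic,
    welch_t,
)
from ptssrisk.exceptions import (
    CollinearityError,
    DegenerateFitError,
    InvalidInputError,
    SeparationError,
    ValidationError,
)


class TestDichotomize:
    def test_upper_tertile_counting(self):
        labels = dichotomize(pd.Series(range(1, 10)), "T_upper_vs_rest")
        assert labels.tolist() == [0, 0, 0, 0, 0, 0, 1, 1, 1]

    def test_quartile_contrast_excludes_middle(self):
        labels = dichotomize(pd.Series(range(1, 9)), "Q4_vs_Q1")
        assert labels[:2].tolist() == [0, 0]
        assert labels[6:].tolist() == [1, 1]
        assert labels[2:6].isna().all()

    def test_tertile_contrast_excludes_middle_third(self):
        labels = dichotomize(pd.Series(range(1, 10)), "T3_vs_T1")
        assert labels.notna().sum() == 6

    def test_high_fraction_near_one_third_on_continuous(self, rng):
        labels = dichotomize(pd.Series(rng.normal(size=3000)), "T_upper_vs_rest")
        assert labels.mean() == pytest.approx(1 / 3, abs=0.02)

    def test_boundary_ties_go_low(self):
        scores = pd.Series([1, 1, 1, 1, 1, 1, 2, 2, 2])
        labels = dichotomize(scores, "T_upper_vs_rest")
        # the cut point value itself belongs to the low group
        cut = np.quantile(scores, 2 / 3)
        assert (labels[scores == cut] == 0).all()

    def test_missing_scores_yield_missing_labels(self):
        labels = dichotomize(pd.Series([1, 2, 3, 4, 5, np.nan]), "T_upper_vs_rest")
        assert np.isnan(labels.iloc[-1])

    def test_degenerate_distribution_raises(self):
        with pytest.raises(DegenerateFitError):
            dichotomize(pd.Series([2.0] * 10), "T_upper_vs_rest")


class TestWelch:
    def test_identical_groups(self):
        r = welch_t([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.t == 0.0
        assert r.p == 1.0

    def test_matches_textbook_formula(self):
        a, b = np.array([1.0, 2, 3, 4]), np.array([2.0, 3, 4, 5])
        r = welch_t(a, b)
        va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 4
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 3)
        p = 2 * stats.t.sf(abs(t), df)
        assert r.t == pytest.approx(t, rel=1e-12)
        assert r.df == pytest.approx(df, rel=1e-12)
        assert r.p == pytest.approx(p, rel=1e-12)

    def test_sign_flips_under_group_exchange(self, rng):
        a, b = rng.normal(size=10), rng.normal(1, 2, size=14)
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_agrees_with_student_under_equal_variance(self, rng):
        a, b = rng.normal(size=400), rng.normal(0.1, 1, size=400)
        r = welch_t(a, b)
        student = stats.ttest_ind(a, b, equal_var=True)
        assert r.p == pytest.approx(student.pvalue, abs=1e-3)

    def test_insufficient_data_raises(self):
        with pytest.raises(InvalidInputError):
            welch_t([1.0], [1, 2, 3])


class TestScreening:
    def test_constant_predictor_excluded(self, rng):
        tab = pd.DataFrame({"flat": np.ones(40), "real": rng.normal(size=40)})
        labels = pd.Series([0.0, 1.0] * 20)
        selected, screen = screen_predictors(tab, labels, ["flat", "real"])
        assert "flat" not in selected
        # identical degenerate groups: no evidence of a difference
        assert (screen.loc[screen.predictor == "flat", "p"] == 1.0).all()

    def test_separated_predictor_included(self, rng):
        labels = pd.Series([0.0] * 64 + [1.0] * 32)
        x = np.concatenate([rng.normal(0, 1, 64), rng.normal(1.2, 1, 32)])
        tab = pd.DataFrame({"x": x})
        selected, _ = screen_predictors(tab, labels, ["x"])
        assert selected == ["x"]

    def test_null_inclusion_rate_near_alpha(self, rng):
        hits = 0
        reps = 400
        labels = pd.Series([0.0] * 64 + [1.0] * 32)
        for _ in range(reps):
            tab = pd.DataFrame({"x": rng.normal(size=96)})
            sel, _ = screen_predictors(tab, labels, ["x"], alpha=0.20)
            hits += bool(sel)
        assert hits / reps == pytest.approx(0.20, abs=0.05)


class TestEmImpute:
    def test_complete_table_returned_unchanged(self, rng):
        tab = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        out = em_impute(tab)
        pd.testing.assert_frame_equal(out, tab)

    def test_bivariate_conditional_mean_closed_form(self, rng):
        # y missing for a random subset; ML factorizes: x moments from all
        # rows, regression of y on x from complete rows; imputations are the
        # complete-case OLS predictions
        n = 200
        x = rng.normal(0, 1, n)
        y = 1.5 + 0.8 * x + rng.normal(0, 0.5, n)
        miss = rng.random(n) < 0.3
        tab = pd.DataFrame({"x": x, "y": np.where(miss, np.nan, y)})
        out = em_impute(tab, tol=1e-10)
        comp = ~miss
        slope, intercept = np.polyfit(x[comp], y[comp], 1)
        expected = intercept + slope * x[miss]
        assert np.allclose(out["y"].to_numpy()[miss], expected, atol=1e-4)
        # observed entries untouched
        assert np.array_equal(out["y"].to_numpy()[comp], y[comp])
        assert np.array_equal(out["x"].to_numpy(), x)

    def test_mcar_mean_consistency(self, rng):
        n = 4000
        x = rng.normal(2.0, 1.0, n)
        y = 1.0 + 0.6 * x + rng.normal(0, 0.8, n)
        miss = rng.random(n) < 0.1
        tab = pd.DataFrame({"x": x, "y": np.where(miss, np.nan, y)})
        out = em_impute(tab)
        assert out["y"].mean() == pytest.approx(1.0 + 0.6 * 2.0, abs=0.05)

    def test_fully_missing_column_raises(self):
        tab = pd.DataFrame({"x": [1.0, 2.0], "y": [np.nan, np.nan]})
        with pytest.raises(ValidationError):
            em_impute(tab)


def _neg_loglik(params, y, X):
    eta = params[0] + X @ params[1:]
    return -np.sum(y * eta - np.log1p(np.exp(eta)))


class TestStepwise:
    def _cohort(self, rng, n, beta=1.2, k_noise=5):
        x = rng.normal(size=n)
        noise = rng.normal(size=(n, k_noise))
        y = (rng.random(n) < expit(-0.5 + beta * x)).astype(float)
        tab = pd.DataFrame(noise, columns=[f"n{i}" for i in range(k_noise)])
        tab["signal"] = x
        return tab, pd.Series(y)

    def test_recovers_generating_predictor(self, rng):
        tab, y = self._cohort(rng, 2000)
        fit = stepwise_logistic(tab, y, list(tab.columns))
        assert "signal" in fit.selected
        coef = next(t for t in fit.terms if t.name == "signal")
        se = abs(coef.coefficient) / np.sqrt(coef.wald_chi_square)
        assert abs(coef.coefficient - 1.2) < 1.96 * se + 0.1

    def test_all_noise_mostly_empty_model(self, rng):
        # with two null candidates at p_enter = 0.15, no term enters in
        # ~0.85^2 = 72% of cohorts
        empty = 0
        for _ in range(30):
            tab = pd.DataFrame(rng.normal(size=(150, 2)), columns=["n0", "n1"])
            y = pd.Series((rng.random(150) < 1 / 3).astype(float))
            fit = stepwise_logistic(tab, y, ["n0", "n1"])
            empty += not fit.selected
        assert empty > 15  # majority of null cohorts select nothing

    def test_coefficients_match_direct_mle_oracle(self, rng):
        # independent oracle: numeric minimization of the negative
        # log-likelihood for the selected design
        tab, y = self._cohort(rng, 800, k_noise=2)
        fit = stepwise_logistic(tab, y, list(tab.columns))
        X = tab[fit.selected].to_numpy()
        res = minimize(
            _neg_loglik, np.zeros(X.shape[1] + 1), args=(y.to_numpy(), X),
            method="BFGS", options={"gtol": 1e-10},
        )
        ours = [fit.intercept] + [t.coefficient for t in fit.terms]
        assert np.allclose(ours, res.x, atol=1e-4)

    def test_separation_raises_named_error(self):
        x = np.concatenate([np.full(20, -2.0), np.full(20, 2.0)]) + np.arange(40) * 1e-4
        y = pd.Series((x > 0).astype(float))
        tab = pd.DataFrame({"x": x})
        with pytest.raises(SeparationError):
            stepwise_logistic(tab, y, ["x"])

    def test_missing_candidates_rejected(self, rng):
        tab, y = self._cohort(rng, 100)
        tab.loc[3, "signal"] = np.nan
        with pytest.raises(ValidationError):
            stepwise_logistic(tab, y, list(tab.columns))


class TestCStatistic:
    def test_perfect_separation_gives_one(self):
        assert c_statistic([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_tie_rule(self):
        assert c_statistic([1.0, 1.0], [0, 1]) == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(8, 60))
            p = rng.random(n).round(1)  # coarse values force ties
            y = (rng.random(n) < 0.4).astype(int)
            if y.min() == y.max():
                continue
            conc = 0.0
            pairs = 0
            for i in range(n):
                for j in range(n):
                    if y[i] == 1 and y[j] == 0:
                        pairs += 1
                        conc += 1.0 if p[i] > p[j] else (0.5 if p[i] == p[j] else 0.0)
            assert c_statistic(p, y) == pytest.approx(conc / pairs, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        p = rng.random(50)
        y = (rng.random(50) < 0.5).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert c_statistic(np.exp(3 * p), y) == pytest.approx(c_statistic(p, y))

    def test_single_class_raises(self):
        with pytest.raises(InvalidInputError):
            c_statistic([0.1, 0.9], [1, 1])


class TestAdjustedFit:
    def _fitted(self, rng, n=600):
        x = rng.normal(size=n)
        y = pd.Series((rng.random(n) < expit(-0.5 + 1.0 * x)).astype(float))
        tab = pd.DataFrame({"x": x})
        tab["time_since_trauma"] = rng.gamma(2.0, 6.0, n)
        tab["severity_rating"] = rng.normal(8, 1.4, n)
        fit = stepwise_logistic(tab, y, ["x"])
        return tab, y, fit

    def test_forced_covariates_always_reported(self, rng):
        tab, y, fit = self._fitted(rng)
        adj = fit_adjusted(fit, tab, y)
        names = [t.name for t in adj.terms]
        assert "time_since_trauma" in names and "severity_rating" in names
        assert all(t.forced for t in adj.terms if t.name != "x")

    def test_independent_covariates_leave_coefficient_stable(self, rng):
        tab, y, fit = self._fitted(rng, n=3000)
        adj = fit_adjusted(fit, tab, y)
        b0 = next(t.coefficient for t in fit.terms if t.name == "x")
        b1 = next(t.coefficient for t in adj.terms if t.name == "x")
        assert b1 == pytest.approx(b0, abs=0.05)

    def test_duplicate_covariate_raises_collinearity(self, rng):
        tab, y, fit = self._fitted(rng)
        tab["dup"] = tab["x"]
        with pytest.raises(CollinearityError):
            fit_adjusted(fit, tab, y, covariates=["dup"])


def test_fit_logistic_drops_missing_rows(rng):
    x = rng.normal(size=300)
    y = pd.Series((rng.random(300) < expit(x)).astype(float))
    tab = pd.DataFrame({"x": x})
    tab.loc[:9, "x"] = np.nan
    fit = fit_logistic(tab, y, ["x"])
    assert fit.n == 290
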