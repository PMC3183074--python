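"""Lifespan estimation, window summaries, OLS/F/l.o.o., diagnostics, KDE
and KS — with independent oracles (ANOVA decomposition, n-refit l.o.o.,
statsmodels cross-check)."""

import numpy as np
import pandas as pd
import pytest

from wormspan import stats as ws
from wormspan.types import BiomarkerTimecourse


class TestLifespanEstimate:
    @pytest.mark.parametrize("ages,alive,expected", [
        ([9, 10, 11], [True, True, False], 10.5),
        ([8, 10, 14], [True, True, False], 12.0),
    ])
    def test_interval_midpoint(self, ages, alive, expected):
        est = ws.estimate_lifespan(ages, alive)
        assert est.lifespan_days == expected
        assert not est.censored

    def test_never_dead_is_censored(self):
        est = ws.estimate_lifespan([3, 4, 5], [True, True, True])
        assert est.censored and est.lifespan_days is None

    def test_dead_at_first_observation_rejected(self):
        with pytest.raises(ValueError, match="bracket"):
            ws.estimate_lifespan([3, 4], [False, False])


class TestWindowSummary:
    def test_linear_series(self):
        tc = BiomarkerTimecourse("a", "length",
                                 np.array([3.0, 4, 5, 6, 7]),
                                 np.array([1.0, 2, 3, 4, 5]))
        s = ws.window_summary(tc)
        assert s.mean == pytest.approx(3.0)
        assert s.slope == pytest.approx(1.0)
        assert s.n_points == 5

    def test_constant_series(self):
        tc = BiomarkerTimecourse("a", "x", np.array([3.0, 5, 7]),
                                 np.array([2.0, 2, 2]))
        s = ws.window_summary(tc)
        assert s.slope == pytest.approx(0.0, abs=1e-12)
        assert s.mean == 2.0

    def test_single_point_slope_undefined(self):
        tc = BiomarkerTimecourse("a", "x", np.array([5.0]), np.array([1.0]))
        s = ws.window_summary(tc)
        assert s.slope is None and s.mean == 1.0

    def test_noisy_planted_slope_recovered(self):
        rng = np.random.default_rng(0)
        true_slope = 0.7
        slopes = []
        for _ in range(50):
            ages = np.arange(3.0, 8.0)
            vals = 2.0 + true_slope * ages + rng.normal(0, 0.3, 5)
            slopes.append(ws.window_summary(
                BiomarkerTimecourse("a", "x", ages, vals)).slope)
        se = np.std(slopes, ddof=1) / np.sqrt(50)
        assert abs(np.mean(slopes) - true_slope) < 2 * se + 1e-9


class TestOls:
    def test_exact_relation(self):
        x = np.arange(20.0)
        res = ws.ols_predict(x[:, None], x)
        assert res.r2 == pytest.approx(1.0)
        assert res.p_value < 1e-30
        assert res.coefficients[0] == pytest.approx(1.0)

    def test_f_formula_example(self):
        # R2 = 0.32, p = 2 predictors, n = 500 -> F = 0.32*497/(0.68*2)
        assert ws.f_from_r2(0.32, 2, 497) == pytest.approx(116.94, abs=0.01)

    def test_f_matches_anova_decomposition(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((120, 3))
        y = X @ np.array([0.5, -0.2, 0.1]) + rng.standard_normal(120)
        res = ws.ols_predict(X, y)
        # brute-force F from sums of squares
        A = np.column_stack([np.ones(120), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        fitted = A @ beta
        ss_model = np.sum((fitted - y.mean()) ** 2)
        ss_err = np.sum((y - fitted) ** 2)
        F_anova = (ss_model / 3) / (ss_err / (120 - 3 - 1))
        assert res.f_statistic == pytest.approx(F_anova, abs=1e-8)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        X = rng.standard_normal((80, 2))
        y = X[:, 0] + 0.3 * rng.standard_normal(80)
        res = ws.ols_predict(X, y)
        smres = sm.OLS(y, sm.add_constant(X)).fit()
        assert res.r2 == pytest.approx(smres.rsquared, abs=1e-10)
        assert res.f_statistic == pytest.approx(smres.fvalue, abs=1e-8)
        assert res.p_value == pytest.approx(smres.f_pvalue, abs=1e-12)

    def test_univariate_r2_is_squared_pearson(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(60)
        y = 0.8 * x + rng.standard_normal(60)
        res = ws.ols_predict(x[:, None], y)
        assert res.r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2,
                                       abs=1e-10)

    def test_permuted_labels_below_null_quantile(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(200)
        y = x + 0.5 * rng.standard_normal(200)
        yp = rng.permutation(y)
        null = [ws.ols_predict(x[:, None], rng.permutation(y)).r2
                for _ in range(100)]
        assert ws.ols_predict(x[:, None], yp).r2 <= np.quantile(null, 0.99)

    def test_collinear_predictors_rejected(self):
        x = np.arange(30.0)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            ws.ols_predict(X, x)


class TestLooR2:
    def test_exact_linear_gives_one(self):
        x = np.linspace(0, 1, 50)
        assert ws.loo_r2(x[:, None], 3 * x + 1) == pytest.approx(1.0)

    def test_matches_naive_refit_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 2))
        y = X[:, 0] - X[:, 1] + rng.standard_normal(40)
        fast = ws.loo_r2(X, y)
        # brute force: refit n times
        preds = np.empty(40)
        for i in range(40):
            keep = np.arange(40) != i
            A = np.column_stack([np.ones(39), X[keep]])
            beta, *_ = np.linalg.lstsq(A, y[keep], rcond=None)
            preds[i] = np.concatenate([[1.0], X[i]]) @ beta
        naive = 1 - np.sum((y - preds) ** 2) / np.sum((y - y.mean()) ** 2)
        assert fast == pytest.approx(naive, abs=1e-10)

    def test_noise_features_loo_below_insample(self):
        rng = np.random.default_rng(6)
        below = 0
        for s in range(20):
            X = rng.standard_normal((30, 5))
            y = rng.standard_normal(30)
            if ws.loo_r2(X, y) <= ws.ols_predict(X, y).r2:
                below += 1
        assert below == 20


class TestSurvivalIndex:
    def _cohort_df(self, n=400, seed=0, only_length=True):
        rng = np.random.default_rng(seed)
        L = rng.normal(10.7, 1.9, n)
        df = pd.DataFrame({"lifespan_days": L})
        for col in ws.SURVIVAL_INDEX_PREDICTORS:
            if only_length and col.startswith("length"):
                df[col] = 0.5 * L + rng.standard_normal(n)
            else:
                df[col] = rng.standard_normal(n)
        return df

    def test_uninformative_predictors_get_small_weights(self):
        df = self._cohort_df()
        res = ws.survival_prediction_index(df)
        for name, w in zip(res.predictors, res.coefficients):
            if not name.startswith("length"):
                assert abs(w) < 0.1

    def test_weights_sorted_by_magnitude(self):
        df = self._cohort_df(seed=1)
        res = ws.survival_prediction_index(df)
        mags = [abs(w) for _, w in res.weights_by_magnitude()]
        assert mags == sorted(mags, reverse=True)

    def test_duplicate_predictor_collinearity_error(self):
        df = self._cohort_df(seed=2)
        df["motion_mean"] = df["motion_slope"]
        with pytest.raises(ValueError, match="collinear"):
            ws.survival_prediction_index(df)

    def test_missing_predictor_rejected(self):
        df = self._cohort_df().drop(columns=["texture_mean"])
        with pytest.raises(ValueError, match="missing"):
            ws.survival_prediction_index(df)


class TestDichotomize:
    def test_perfect_predictions(self):
        rng = np.random.default_rng(0)
        y = rng.normal(10, 2, 100)
        t = ws.dichotomize_test(y, y)
        assert t.sensitivity == 1.0 and t.specificity == 1.0

    def test_independent_predictions_near_chance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(10, 2, 1000)
        p = rng.normal(10, 2, 1000)
        t = ws.dichotomize_test(p, y)
        assert abs(t.sensitivity - 0.5) < 0.05
        assert abs(t.specificity - 0.5) < 0.05

    def test_balanced_on_symmetric_cohorts(self):
        rng = np.random.default_rng(2)
        y = rng.normal(10, 2, 1000)
        p = 0.6 * y + rng.normal(0, 1.0, 1000)
        t = ws.dichotomize_test(p, y)
        assert abs(t.sensitivity - t.specificity) < 0.05


class TestKdeAndKs:
    def test_kernel_variance_formula(self):
        rng = np.random.default_rng(0)
        data = rng.normal(10.7, 1.9, 100)
        kde = ws.lifespan_kde(data)
        assert kde.kernel_variance == pytest.approx(
            data.var(ddof=1) * 100 ** -0.2)

    def test_density_nonnegative_integrates_to_one(self):
        rng = np.random.default_rng(1)
        kde = ws.lifespan_kde(rng.normal(10, 2, 200))
        grid = kde.grid(2048)
        dens = kde(grid)
        assert (dens >= 0).all()
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_bimodal_mixture_two_modes(self):
        rng = np.random.default_rng(2)
        data = np.concatenate([rng.normal(8, 0.7, 300),
                               rng.normal(14, 0.7, 300)])
        kde = ws.lifespan_kde(data)
        grid = kde.grid(1024)
        dens = kde(grid)
        peaks = np.flatnonzero((dens[1:-1] > dens[:-2])
                               & (dens[1:-1] > dens[2:]))
        assert peaks.size >= 2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ws.lifespan_kde(np.full(10, 3.0))

    def test_ks_identical_and_disjoint(self):
        a = np.arange(50.0)
        stat, p = ws.ks_compare(a, a)
        assert stat == 0.0 and p == 1.0
        stat, _ = ws.ks_compare(a, a + 100)
        assert stat == 1.0


class TestPartialR2:
    def test_controlling_for_itself_removes_everything(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.standard_normal(200)})
        y = df["x"] + 0.5 * rng.standard_normal(200)
        table = ws.partial_r2_table(df, y, ["x"], {"self": ["x"]})
        assert table.loc["x", "self"] == pytest.approx(0.0, abs=1e-6)

    def test_independent_control_leaves_r2(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.standard_normal(1000),
                           "c": rng.standard_normal(1000)})
        y = df["x"] + 0.5 * rng.standard_normal(1000)
        table = ws.partial_r2_table(df, y, ["x"], {"c": ["c"]})
        assert table.loc["x", "c"] == pytest.approx(100.0, abs=10.0)

    def test_chain_mediation_asymmetry(self):
        # C -> M -> L: controlling M removes most of C's R2 on L, but
        # controlling C leaves much of M's
        rng = np.random.default_rng(2)
        C = rng.standard_normal(2000)
        M = 0.9 * C + 0.5 * rng.standard_normal(2000)
        L = 0.9 * M + 0.5 * rng.standard_normal(2000)
        df = pd.DataFrame({"C": C, "M": M})
        table = ws.partial_r2_table(df, L, ["C", "M"],
                                    {"other": []})
        t2 = ws.partial_r2_table(df, L, ["C"], {"M": ["M"]})
        t3 = ws.partial_r2_table(df, L, ["M"], {"C": ["C"]})
        assert t2.loc["C", "M"] < 10.0
        assert t3.loc["M", "C"] > 25.0
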