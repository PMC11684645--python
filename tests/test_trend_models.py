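import math

import numpy as np
import pandas as pd
import pytest

from mhtrends.trend_models import (SingleClassError, diagnostics, fit_logistic,
                                   fit_paper_models, moments, pearson_trend,
                                   vif)


def table_2x2_design(a, b, c, d):
    """Grouped data for a 2x2 table: a/b events/non-events among exposed,
    c/d among unexposed. Returns (y, x, weights)."""
    y = np.array([1, 0, 1, 0], dtype=float)
    x = np.array([1, 1, 0, 0], dtype=float)
    w = np.array([a, b, c, d], dtype=float)
    return y, x, w


class TestLogisticClosedForm:
    def test_worked_2x2_example(self):
        # exposed 20/30, unexposed 10/40: OR = 20*40/(30*10) = 2.6667
        y, x, w = table_2x2_design(20, 30, 10, 40)
        fit = fit_logistic(y, x, names=["exposure"], sample_weight=w)
        assert fit["exposure"].exp_b == pytest.approx(20 * 40 / (30 * 10), abs=1e-4)
        se = math.sqrt(1 / 20 + 1 / 30 + 1 / 10 + 1 / 40)
        assert fit["exposure"].se == pytest.approx(se, abs=1e-4)

    def test_random_tables_match_woolf_formulas(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 200, size=4)
            y, x, w = table_2x2_design(a, b, c, d)
            fit = fit_logistic(y, x, names=["exposure"], sample_weight=w)
            assert fit["exposure"].b == pytest.approx(math.log(a * d / (b * c)), abs=1e-6)
            assert fit["exposure"].se == pytest.approx(
                math.sqrt(1 / a + 1 / b + 1 / c + 1 / d), abs=1e-6)

    def test_balanced_independence_gives_or_one(self):
        y, x, w = table_2x2_design(15, 35, 15, 35)
        fit = fit_logistic(y, x, names=["exposure"], sample_weight=w)
        assert fit["exposure"].exp_b == pytest.approx(1.0, abs=1e-9)

    def test_single_class_outcome_errors(self):
        with pytest.raises(SingleClassError):
            fit_logistic(np.ones(20), np.arange(20.0))


class TestLogisticAgainstGlmOracle:
    def test_agrees_with_statsmodels_on_random_data(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(80, 300))
            k = int(rng.integers(1, 4))
            X = rng.normal(size=(n, k))
            beta = rng.normal(scale=0.8, size=k)
            p = 1 / (1 + np.exp(-(0.3 + X @ beta)))
            y = rng.binomial(1, p)
            if y.min() == y.max():
                continue
            fit = fit_logistic(y, X)
            ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit(tol=1e-12)
            mine = [fit["intercept"].b] + [fit[f"x{j+1}"].b for j in range(k)]
            mine_se = [fit["intercept"].se] + [fit[f"x{j+1}"].se for j in range(k)]
            np.testing.assert_allclose(mine, ref.params, atol=1e-6)
            np.testing.assert_allclose(mine_se, ref.bse, atol=1e-6)
            assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-6)


class TestLogisticInference:
    @pytest.fixture(scope="class")
    @staticmethod
    def fit():
        rng = np.random.default_rng(1)
        n = 500
        X = np.column_stack([rng.binomial(1, 0.4, n), rng.normal(size=n)])
        p = 1 / (1 + np.exp(-(-1.0 + 0.8 * X[:, 0] + 0.5 * X[:, 1])))
        y = rng.binomial(1, p)
        return fit_logistic(y, X, names=["flag", "cont"])

    def test_ci_brackets_odds_ratio(self, fit):
        for c in fit.coefficients.values():
            if c.se > 0:
                assert c.ci_low_exp_b < c.exp_b < c.ci_high_exp_b
                assert c.ci_low_exp_b == pytest.approx(math.exp(c.b - 1.96 * c.se))

    def test_wald_is_z_squared_and_flag_gives_z(self, fit):
        c = fit["flag"]
        assert c.wald == pytest.approx(c.z ** 2)

    def test_lrt_nonnegative_and_consistent_with_reduced_ll(self, fit):
        for name in ("flag", "cont"):
            c = fit[name]
            assert c.lrt_stat >= 0
            assert c.lrt_stat == pytest.approx(
                2 * (fit.log_likelihood - c.ll_reduced), abs=1e-6)
            assert 0 < c.lrt_p <= 1

    def test_log_likelihood_nonpositive(self, fit):
        assert fit.log_likelihood <= 0

    def test_quasi_separation_flagged_not_raised(self):
        # covariate perfectly predicts the outcome
        x = np.repeat([0.0, 1.0], 50)
        y = np.repeat([0, 1], 50)
        fit = fit_logistic(y, x, names=["sep"])
        assert not fit.converged
        assert any("separation" in w or "converge" in w for w in fit.warnings)


class TestPaperModelLayouts:
    def test_fits_both_layouts_per_outcome(self):
        rng = np.random.default_rng(2)
        n = 400
        rows = pd.DataFrame({
            "start_year": rng.integers(1990, 2023, n),
            "covid": 0, "complete": rng.binomial(1, 0.6, n),
        })
        rows["covid"] = (rows["start_year"] >= 2020).astype(int)
        for t in ("depression", "anxiety", "loneliness", "distress"):
            rows[f"{t}_mention"] = rng.binomial(1, 0.2, n)
        rows["any_word"] = rows[[f"{t}_mention" for t in
                                 ("depression", "anxiety", "loneliness", "distress")]].max(axis=1)
        report = fit_paper_models(rows)
        assert set(report) == {"depression", "anxiety", "loneliness", "distress", "any_word"}
        for fits in report.values():
            assert set(fits) == {"multivariable", "year"}
            assert set(fits["multivariable"].coefficients) == {"intercept", "covid", "complete"}

    def test_single_class_outcome_skipped(self):
        rows = pd.DataFrame({
            "start_year": [2019, 2020, 2021, 2018] * 25,
            "covid": [0, 1, 1, 0] * 25, "complete": [1, 0, 1, 0] * 25,
            "depression_mention": [0, 1, 0, 1] * 25,
            "loneliness_mention": 0,
        })
        rows["any_word"] = rows["depression_mention"]
        report = fit_paper_models(rows, outcomes=("depression", "loneliness", "any_word"))
        assert "loneliness" not in report and "depression" in report


class TestPearsonTrend:
    def _rows(self, points, status="Completed"):
        return pd.DataFrame([{"start_year": x, "status": status,
                              "anxiety_frequency": f} for x, f in points])

    def test_perfect_linearity(self):
        tc = pearson_trend(self._rows([(1, 2), (2, 4), (3, 6)]), "anxiety",
                           "Completed", mode="per-trial")
        assert tc.r == pytest.approx(1.0)

    def test_constant_frequency_not_computable(self):
        tc = pearson_trend(self._rows([(1, 2), (2, 2), (3, 2)]), "anxiety",
                           "Completed", mode="per-trial")
        assert not tc.computable and math.isnan(tc.r)

    def test_matches_direct_covariance_formula(self):
        pts = [(1998, 0.0), (2004, 0.013), (2010, 0.002), (2016, 0.021), (2022, 0.034)]
        x = np.array([p[0] for p in pts], float)
        f = np.array([p[1] for p in pts], float)
        expected = (np.mean((x - x.mean()) * (f - f.mean()))
                    / (x.std() * f.std()))
        tc = pearson_trend(self._rows(pts), "anxiety", "Completed", mode="per-trial")
        assert tc.r == pytest.approx(expected, abs=1e-12)

    def test_per_year_mean_mode_averages_within_year(self):
        rows = self._rows([(2000, 0.0), (2000, 0.2), (2001, 0.2), (2001, 0.4),
                           (2002, 0.4), (2002, 0.6)])
        tc = pearson_trend(rows, "anxiety", "Completed", mode="per-year-mean")
        assert tc.n_points == 3 and tc.r == pytest.approx(1.0)


class TestDiagnostics:
    def test_perfect_test(self):
        flags = np.array([0, 1, 0, 1, 1])
        d = diagnostics(flags, flags)
        assert d.sensitivity == 100.0 and d.specificity == 100.0

    def test_hand_counted_cells(self):
        pred = np.array([1] * 5 + [0] * 5 + [0] * 8 + [1] * 2)
        outc = np.array([1] * 5 + [1] * 5 + [0] * 8 + [0] * 2)
        d = diagnostics(pred, outc)
        assert (d.tp, d.fn, d.tn, d.fp) == (5, 5, 8, 2)
        assert d.sensitivity == pytest.approx(50.0)
        assert d.specificity == pytest.approx(80.0)

    def test_no_positive_outcomes_flagged(self):
        d = diagnostics(np.array([0, 1, 0]), np.zeros(3, dtype=int))
        assert d.flagged and math.isnan(d.sensitivity)

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(8)
        p, o = rng.integers(0, 2, 100), rng.integers(0, 2, 100)
        d = diagnostics(p, o)
        assert d.tp + d.fp + d.tn + d.fn == 100


class TestVif:
    def test_orthogonal_predictors_are_one(self):
        X = np.array([[1, 0], [1, 0], [-1, 0], [-1, 0],
                      [0, 1], [0, -1], [0, 1], [0, -1]], dtype=float)
        v = vif(X, names=["a", "b"])
        assert v["a"] == pytest.approx(1.0, abs=1e-9)
        assert v["b"] == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_predictor_flagged_infinite(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        v = vif(np.column_stack([x, x]), names=["a", "a_copy"])
        assert math.isinf(v["a"]) and math.isinf(v["a_copy"])

    def test_matches_correlation_matrix_inverse_oracle(self):
        rng = np.random.default_rng(10)
        cov = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.5], [0.3, 0.5, 1.0]])
        X = rng.multivariate_normal(np.zeros(3), cov, size=4000)
        v = vif(X, names=["a", "b", "c"])
        # oracle: diagonal of the inverse sample correlation matrix
        R = np.corrcoef(X, rowvar=False)
        expected = np.diag(np.linalg.inv(R))
        for name, exp in zip(("a", "b", "c"), expected):
            assert v[name] == pytest.approx(exp, rel=1e-9)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            vif(np.column_stack([np.ones(10), np.arange(10.0)]))


class TestMoments:
    def test_bernoulli_quarter_proportion_matches_analytic_skewness(self):
        # n = 400 with exactly 100 ones: g1 = (1-2p)/sqrt(p(1-p)) = 1.1547
        x = np.array([1] * 100 + [0] * 300)
        m = moments(x)
        p = 0.25
        assert m.skewness == pytest.approx((1 - 2 * p) / math.sqrt(p * (1 - p)), abs=1e-3)
        assert m.excess_kurtosis == pytest.approx(
            (1 - 6 * p * (1 - p)) / (p * (1 - p)), abs=1e-3)

    def test_balanced_binary_has_zero_skew(self):
        m = moments(np.array([0, 1] * 50))
        assert m.skewness == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("p", [0.05, 0.1, 0.2])
    def test_rare_flags_are_right_skewed_and_leptokurtic(self, p):
        n = 1000
        x = np.array([1] * int(p * n) + [0] * (n - int(p * n)))
        m = moments(x)
        assert m.skewness > 0
        assert m.excess_kurtosis > 0  # p < 0.2113 on both tails

    def test_zero_variance_flagged(self):
        m = moments(np.zeros(10))
        assert m.flagged and math.isnan(m.skewness)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            moments([0, 1, 1])
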