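import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from ratioimpute import (
    SRS,
    DEFAULT_BETA,
    MethodConfig,
    MissingPattern,
    RatioImputationRegressor,
    Sample,
    adjustment_factor,
    build_context,
    default_methods,
    estimate_population_mean,
    fit_regression,
    make_response,
    predict_with_imputation,
    quartiles,
    series_mean_fill,
)
from ratioimpute.exceptions import (
    DegenerateDataError,
    InvalidSpecError,
    NumericDomainError,
)
from ratioimpute.imputers import ImputationContext

from _oracles import interp_quantile, naive_impute


def make_context(**overrides):
    base = dict(
        xbar1_n=3.0, xbar1_r=3.0, xbar2_n=6.0, xbar2_r=4.0,
        q1_x1=2.0, q3_x1=4.0, q1_x2=2.0, q3_x2=8.0, r=10, k=2,
    )
    base.update(overrides)
    return ImputationContext(**base)


class TestSeriesMeanFill:
    def test_fills_with_observed_mean(self):
        out = series_mean_fill([1.0, 2.0, 3.0, np.nan])
        np.testing.assert_allclose(out, [1.0, 2.0, 3.0, 2.0])

    def test_empty_pattern_is_identity(self):
        x = np.array([5.0, 6.0, 7.0])
        np.testing.assert_array_equal(series_mean_fill(x, MissingPattern((), 3)), x)

    def test_single_observed_value(self):
        np.testing.assert_allclose(series_mean_fill([5.0, np.nan, np.nan]), [5.0, 5.0, 5.0])

    def test_all_missing_rejected(self):
        with pytest.raises(DegenerateDataError):
            series_mean_fill([np.nan, np.nan])


class TestQuartiles:
    def test_hand_example(self):
        assert quartiles([1, 2, 3, 4, 5]) == (2.0, 4.0)

    def test_constant_vector(self):
        assert quartiles([3.0] * 6) == (3.0, 3.0)

    def test_monotone(self, rng):
        for _ in range(20):
            q1, q3 = quartiles(rng.normal(size=rng.integers(4, 30)))
            assert q1 <= q3

    def test_matches_independent_interpolation(self, rng):
        x = rng.normal(5, 2, 17)
        q1, q3 = quartiles(x)
        assert q1 == pytest.approx(interp_quantile(x, 0.25), abs=1e-12)
        assert q3 == pytest.approx(interp_quantile(x, 0.75), abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(DegenerateDataError):
            quartiles([1.0, 2.0, 3.0])


class TestFitRegression:
    def test_noiseless_recovery(self, rng):
        x1 = rng.normal(3, 1.5, 30)
        x2 = rng.normal(5, 2, 30)
        y = 0.5 + x1 - 0.3 * x2
        coeffs, yhat = fit_regression(x1, x2, y)
        np.testing.assert_allclose(coeffs, (0.5, 1.0, -0.3), atol=1e-10)
        np.testing.assert_allclose(yhat, y, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        x1 = rng.normal(size=50)
        x2 = rng.normal(size=50)
        y = rng.normal(size=50)
        _, yhat = fit_regression(x1, x2, y)
        resid = y - yhat
        for col in (np.ones(50), x1, x2):
            assert abs(resid @ col) < 1e-8

    def test_monte_carlo_recovery_within_3_se(self):
        rng = np.random.default_rng(99)
        x1 = rng.normal(3, 1.5, 500)
        x2 = rng.normal(5, 2, 500)
        y = make_response(x1, x2, rng.normal(0, 1, 500), DEFAULT_BETA)
        coeffs, yhat = fit_regression(x1, x2, y)
        X = np.column_stack([np.ones(500), x1, x2])
        sigma2 = np.sum((y - yhat) ** 2) / (500 - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        np.testing.assert_array_less(np.abs(np.array(coeffs) - (0.5, 1.0, -0.3)), 3 * se)

    def test_rank_deficient_rejected(self):
        x1 = np.arange(10.0)
        with pytest.raises(NumericDomainError):
            fit_regression(x1, 2 * x1, x1)


class TestBuildContext:
    def test_hand_arithmetic(self):
        x1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        x2 = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        pattern = MissingPattern((5,), 6)
        ctx = build_context(x1, x2, np.where(pattern.mask(), np.nan, x2), pattern)
        assert ctx.xbar2_n == pytest.approx(7.0)
        assert ctx.xbar2_r == pytest.approx(6.0)
        assert ctx.xbar1_n == ctx.xbar1_r == pytest.approx(3.5)
        assert (ctx.r, ctx.k) == (5, 1)

    def test_empty_pattern_no_drift(self, rng):
        x1 = rng.normal(size=8)
        x2 = rng.normal(5, 2, 8)
        ctx = build_context(x1, x2, x2, MissingPattern((), 8))
        assert ctx.xbar2_n == ctx.xbar2_r
        assert ctx.k == 0

    def test_too_few_responding_rejected(self):
        x = np.arange(6.0)
        pattern = MissingPattern((0, 1, 2), 6)
        with pytest.raises(DegenerateDataError):
            build_context(x, x + 1, np.where(pattern.mask(), np.nan, x + 1), pattern)


class TestAdjustmentFactor:
    @pytest.mark.parametrize("cfg", default_methods(), ids=lambda c: c.name)
    def test_no_drift_gives_unit_factor(self, cfg):
        ctx = make_context(xbar2_n=4.0, xbar2_r=4.0)
        assert adjustment_factor(ctx, cfg) == pytest.approx(1.0)

    def test_ratio_hand_value(self):
        ctx = make_context()  # xbar2_n=6, xbar2_r=4, q1_x2=2
        cfg = MethodConfig("ratio", "q1")
        assert adjustment_factor(ctx, cfg) == pytest.approx(8 / 6)

    def test_chain_hand_value(self):
        cfg = MethodConfig("chain", "q1", alpha=0.9)
        assert adjustment_factor(make_context(), cfg) == pytest.approx((4 / 3) ** 0.9)

    def test_chain_zero_exponent_is_unity(self):
        cfg = MethodConfig("chain", "q1", alpha=0.0)
        assert adjustment_factor(make_context(), cfg) == pytest.approx(1.0)

    def test_mratio_collapses_to_ratio(self):
        ctx = make_context()
        collapsed = MethodConfig("mratio", "q1", eps_w=(0.0, 1.0))
        assert adjustment_factor(ctx, collapsed) == pytest.approx(
            adjustment_factor(ctx, MethodConfig("ratio", "q1"))
        )

    def test_mchain_collapses_to_ratio(self):
        ctx = make_context()
        collapsed = MethodConfig("mchain", "q1", alpha=1.0, omega_w=(0.0, 1.0))
        assert adjustment_factor(ctx, collapsed) == pytest.approx(
            adjustment_factor(ctx, MethodConfig("ratio", "q1"))
        )

    def test_mratio_is_affine_in_x2_term(self):
        """x1 is never masked, so mratio = e1 + e2 * f(x2) exactly."""
        ctx = make_context()
        f2 = adjustment_factor(ctx, MethodConfig("ratio", "q1"))
        got = adjustment_factor(ctx, MethodConfig("mratio", "q1", eps_w=(0.9, 0.1)))
        assert got == pytest.approx(0.9 + 0.1 * f2)

    def test_factor_tends_to_one_as_quartile_grows(self):
        """Larger shifts damp the ratio monotonically towards 1."""
        factors = [
            adjustment_factor(make_context(q1_x2=q), MethodConfig("ratio", "q1"))
            for q in (1e2, 1e4, 1e6)
        ]
        assert factors[0] > factors[1] > factors[2] > 1.0
        assert factors[2] == pytest.approx(1.0, abs=1e-5)

    def test_nonpositive_denominator_rejected(self):
        ctx = make_context(xbar2_r=-3.0, q1_x2=2.0)
        with pytest.raises(NumericDomainError):
            adjustment_factor(ctx, MethodConfig("ratio", "q1"))

    @given(
        drift=st.floats(-0.5, 0.5),
        base=st.floats(3.0, 8.0),
        q=st.floats(0.0, 10.0),
        alpha=st.floats(0.0, 1.0),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_chain_between_unity_and_ratio(self, drift, base, q, alpha):
        """The chain exponent in [0, 1] interpolates between 1 and the ratio."""
        ctx = make_context(xbar2_n=base + drift, xbar2_r=base, q1_x2=q)
        f_ratio = adjustment_factor(ctx, MethodConfig("ratio", "q1"))
        f_chain = adjustment_factor(ctx, MethodConfig("chain", "q1", alpha=alpha))
        lo, hi = sorted((1.0, f_ratio))
        assert lo - 1e-12 <= f_chain <= hi + 1e-12


class TestMethodConfig:
    def test_defaults_match_tuned_constants(self):
        by_name = {m.name: m for m in default_methods()}
        assert by_name["ar-crq1"].alpha == 0.90
        assert by_name["ar-mrq1"].eps_w == (0.90, 0.10)
        assert by_name["ar-mcrq1"].alpha == 0.10
        assert by_name["ar-mcrq1"].omega_w == (0.10, 0.90)

    def test_name_round_trip(self):
        for cfg in default_methods():
            assert MethodConfig.from_name(cfg.name) == cfg

    def test_bad_weights_rejected(self):
        with pytest.raises(InvalidSpecError):
            MethodConfig("mratio", "q1", eps_w=(0.7, 0.7))

    def test_unknown_name_rejected(self):
        with pytest.raises(InvalidSpecError):
            MethodConfig.from_name("knn")


def six_row_sample():
    x1 = np.arange(1.0, 7.0)
    x2 = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
    y = make_response(x1, x2, np.zeros(6), DEFAULT_BETA)
    return Sample(x1, x2, y, SRS), MissingPattern((5,), 6)


class TestPredictWithImputation:
    def test_empty_pattern_keeps_regression(self, rng):
        x1 = rng.normal(3, 1.5, 12)
        x2 = rng.normal(5, 2, 12)
        y = make_response(x1, x2, rng.normal(size=12), DEFAULT_BETA)
        sample = Sample(x1, x2, y, SRS)
        for cfg in default_methods():
            pred = predict_with_imputation(sample, MissingPattern((), 12), cfg)
            np.testing.assert_allclose(pred.yhat, pred.yhat_reg)
            assert pred.factor == pytest.approx(1.0)

    def test_worked_six_row_example(self):
        """End-to-end hand computation: fill mean 6, exact OLS fit, factor 11/10."""
        sample, pattern = six_row_sample()
        pred = predict_with_imputation(sample, pattern, MethodConfig("ratio", "q1"))
        # y = 0.5 + 0.4*x1 exactly, so the OLS stage reproduces y
        np.testing.assert_allclose(pred.yhat_reg, sample.y, atol=1e-10)
        # xbar2_n = 7, xbar2_r = 6, q1(obs x2) = 4 -> factor (7+4)/(6+4)
        assert pred.factor == pytest.approx(1.1)
        np.testing.assert_allclose(pred.yhat[:5], sample.y[:5], atol=1e-10)
        assert pred.yhat[5] == pytest.approx(2.9 * 1.1)

    def test_worked_example_q3_variant(self):
        sample, pattern = six_row_sample()
        pred = predict_with_imputation(sample, pattern, MethodConfig("ratio", "q3"))
        # q3 of observed x2 [2,4,6,8,10] is 8 -> factor (7+8)/(6+8)
        assert pred.factor == pytest.approx(15 / 14)
        assert pred.yhat[5] == pytest.approx(2.9 * 15 / 14)

    def test_quartile_variants_share_regression_stage(self, rng):
        """Paired invariant: Q1 and Q3 differ only at masked positions."""
        x1 = rng.normal(3, 1.5, 40)
        x2 = rng.normal(5, 2, 40)
        y = make_response(x1, x2, rng.normal(size=40), DEFAULT_BETA)
        sample = Sample(x1, x2, y, SRS)
        pattern = MissingPattern(tuple(range(8)), 40)
        p1 = predict_with_imputation(sample, pattern, MethodConfig("ratio", "q1"))
        p3 = predict_with_imputation(sample, pattern, MethodConfig("ratio", "q3"))
        np.testing.assert_array_equal(p1.yhat_reg, p3.yhat_reg)
        mask = pattern.mask()
        np.testing.assert_array_equal(p1.yhat[~mask], p3.yhat[~mask])
        assert not np.allclose(p1.yhat[mask], p3.yhat[mask])

    @pytest.mark.parametrize("cfg", default_methods(), ids=lambda c: c.name)
    def test_agrees_with_first_principles_oracle(self, cfg):
        """100 random small instances against an independent re-implementation."""
        rng = np.random.default_rng(314)
        for _ in range(100):
            n = int(rng.integers(8, 21))
            x1 = rng.normal(3, 1.5, n)
            x2 = rng.normal(5, 2, n)
            y = make_response(x1, x2, rng.normal(size=n), DEFAULT_BETA)
            k = int(rng.integers(1, n - 5))
            idx = tuple(int(i) for i in rng.choice(n, k, replace=False))
            sample = Sample(x1, x2, y, SRS)
            pred = predict_with_imputation(sample, MissingPattern(idx, n), cfg)
            expected_yhat, expected_f = naive_impute(
                x1, x2, y, idx, cfg.family, cfg.quartile,
                alpha=cfg.alpha, eps=cfg.eps_w, omega=cfg.omega_w,
            )
            assert pred.factor == pytest.approx(expected_f, abs=1e-10)
            np.testing.assert_allclose(pred.yhat, expected_yhat, atol=1e-10)


class TestEstimatorAPI:
    def test_clone_and_get_params(self):
        est = RatioImputationRegressor(method="ar-crq3", alpha=0.5)
        cloned = clone(est)
        assert cloned.get_params()["method"] == "ar-crq3"
        assert cloned.get_params()["alpha"] == 0.5

    def test_fit_predict_round_trip(self, rng):
        x1 = rng.normal(3, 1.5, 30)
        x2 = rng.normal(5, 2, 30)
        y = make_response(x1, x2, rng.normal(size=30), DEFAULT_BETA)
        X = np.column_stack([x1, x2])
        X[:3, 1] = np.nan
        est = RatioImputationRegressor(method="r-rq1", complete_mean=5.0).fit(X, y)
        np.testing.assert_allclose(est.predict(X), est.fitted_values_)
        assert est.missing_mask_.sum() == 3

    def test_without_reference_mean_factor_is_one(self, rng):
        """On real data with no complete column the adjustment is inert."""
        x1 = rng.normal(3, 1.5, 20)
        x2 = rng.normal(5, 2, 20)
        y = make_response(x1, x2, rng.normal(size=20), DEFAULT_BETA)
        X = np.column_stack([x1, x2])
        X[:4, 1] = np.nan
        est = RatioImputationRegressor(method="r-rq1").fit(X, y)
        assert est.factor_ == pytest.approx(1.0)

    def test_missing_x1_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        X[0, 0] = np.nan
        with pytest.raises(InvalidSpecError):
            RatioImputationRegressor().fit(X, np.arange(10.0))


class TestPopulationMeanEstimators:
    def test_ratio_identity_when_means_match(self):
        assert estimate_population_mean(10.0, 5.0, 5.0) == pytest.approx(10.0)

    def test_quartile_shift_hand_value(self):
        got = estimate_population_mean(10.0, 5.0, 4.0, q=2.0)
        assert got == pytest.approx(10 * 7 / 6)

    def test_chain_alpha_one_equals_ratio(self):
        ratio = estimate_population_mean(10.0, 5.0, 4.0, q=2.0)
        chain = estimate_population_mean(10.0, 5.0, 4.0, q=2.0, family="chain", alpha=1.0)
        assert chain == pytest.approx(ratio)

    def test_multivariate_weight_collapse(self):
        ratio = estimate_population_mean(10.0, 5.0, 4.0, q=2.0)
        mr = estimate_population_mean(
            10.0, 3.0, 3.0, q=1.0, family="mratio",
            weights=(0.0, 1.0), second_var=(5.0, 4.0, 2.0),
        )
        assert mr == pytest.approx(ratio)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(NumericDomainError):
            estimate_population_mean(10.0, 5.0, -4.0, q=2.0)
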