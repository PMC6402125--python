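"""Regression-engine tests against closed-form 2x2 oracles.

For a treatment-only logistic model on a 2x2 table with +/-1 coding, the
MLE treatment coefficient is half the log odds ratio, and the Firth
estimate is half the log odds ratio after adding 1/2 to every cell.
These closed forms are computed inline and serve as independent oracles
for the iterative fitters.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from copkit import (RegressionData, TwoByTwo, fit_cauchy_wip, fit_firth,
                    fit_linear_gaussian, fit_logistic_mle, fit_two_by_two,
                    wald_test)
from copkit.glm import PenalizedLogit


def half_log_or(ec, ev, n=10):
    """Half log odds ratio of a 2x2 (the +/-1-coded MLE closed form)."""
    return 0.5 * np.log((ev / (n - ev)) / (ec / (n - ec)))


def firth_half_log_or(ec, ev, n=10):
    """Half the add-1/2-to-each-cell log odds ratio (Firth closed form)."""
    return 0.5 * np.log(((ev + 0.5) * (n - ec + 0.5)) /
                        ((n - ev + 0.5) * (ec + 0.5)))


def table(ec, ev, n=10):
    return TwoByTwo(n, n, ec, ev)


class TestLogisticMLE:
    def test_matches_closed_form_on_non_separated_tables(self):
        for ec in range(1, 10):
            for ev in range(1, 10):
                fit = fit_two_by_two(table(ec, ev), "logistic", "pm1")
                assert not fit.diverged
                assert fit.params["treatment"] == pytest.approx(
                    half_log_or(ec, ev), abs=1e-6)

    def test_woolf_standard_error(self):
        # Woolf formula on the +/-1 scale: 0.5*sqrt(sum of reciprocal cells)
        fit = fit_two_by_two(table(2, 3), "logistic", "pm1")
        se_oracle = 0.5 * np.sqrt(1 / 2 + 1 / 8 + 1 / 3 + 1 / 7)
        assert fit.bse["treatment"] == pytest.approx(se_oracle, rel=1e-6)
        z, p = wald_test(fit, "treatment")
        assert p > 0.05

    def test_matches_statsmodels_on_general_design(self):
        rng = np.random.default_rng(2)
        X = np.c_[np.ones(400), rng.normal(size=400), rng.binomial(1, .5, 400)]
        y = rng.binomial(1, 1 / (1 + np.exp(-(X @ [-0.5, 0.7, -1.0]))))
        ours = fit_logistic_mle(
            RegressionData(y, pd.DataFrame(X, columns=["c", "x1", "x2"])))
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(ours.params.to_numpy(), ref.params, atol=1e-8)
        np.testing.assert_allclose(ours.bse.to_numpy(), ref.bse, atol=1e-8)

    @pytest.mark.parametrize("ec,ev", [(0, 0), (1, 0), (0, 4), (10, 0), (10, 10)])
    def test_separated_tables_flagged_diverged(self, ec, ev):
        fit = fit_two_by_two(table(ec, ev), "logistic", "pm1")
        assert fit.diverged and not fit.converged
        assert np.all(np.isfinite(fit.params))  # last iterate, not NaN
        assert np.max(np.diag(fit.cov_params)) > 1e3  # "infinite" variance

    def test_all_zero_outcome_diverges(self):
        y = np.zeros(20)
        X = pd.DataFrame({"c": np.ones(20), "z": np.r_[-np.ones(10), np.ones(10)]})
        assert fit_logistic_mle(RegressionData(y, X)).diverged

    def test_non_binary_outcome_rejected(self):
        X = pd.DataFrame({"c": np.ones(4)})
        with pytest.raises(ValueError, match="binary"):
            fit_logistic_mle(RegressionData([0.0, 0.5, 1.0, 1.0], X))

    def test_rank_deficient_design_rejected(self):
        X = pd.DataFrame({"c": np.ones(8), "c2": np.ones(8)})
        with pytest.raises(ValueError, match="rank"):
            fit_logistic_mle(RegressionData(np.r_[np.zeros(4), np.ones(4)], X))


class TestFirth:
    def test_matches_half_cell_closed_form_everywhere(self):
        # the Jeffreys penalty keeps every pattern finite, including full
        # separation
        for ec in range(11):
            for ev in range(11):
                fit = fit_two_by_two(table(ec, ev), "firth", "pm1")
                assert not fit.diverged
                assert fit.params["treatment"] == pytest.approx(
                    firth_half_log_or(ec, ev), abs=1e-3)

    def test_variance_is_inverse_fisher_information_at_estimate(self):
        # zero-event table: p_hat = 0.5/11 per arm, slope variance
        # 1/(20 p (1-p))
        fit = fit_two_by_two(table(0, 0), "firth", "pm1")
        p = 0.5 / 11
        assert fit.cov_params.loc["treatment", "treatment"] == pytest.approx(
            1 / (20 * p * (1 - p)), rel=1e-4)

    def test_penalized_objective_ascends(self):
        fit = fit_two_by_two(table(9, 0), "firth", "pm1")
        trace = np.asarray(fit.objective_trace)
        assert np.all(np.diff(trace) >= -1e-10)


class TestCauchyWIP:
    def test_symmetric_tables_give_zero(self):
        for ec in (0, 1, 5):
            fit = fit_two_by_two(table(ec, ec), "wip", "pm1")
            assert abs(fit.params["treatment"]) < 1e-8

    def test_always_finite_even_under_separation(self):
        for ec, ev in [(0, 0), (10, 0), (0, 10), (1, 0)]:
            fit = fit_two_by_two(table(ec, ev), "wip", "pm1")
            assert not fit.diverged
            assert np.all(np.isfinite(fit.params))

    def test_shrinks_toward_zero_relative_to_mle(self):
        # over every non-separated table the weakly informative prior
        # pulls the estimate toward zero
        for ec in range(1, 10):
            for ev in range(1, 10):
                if ec == ev:
                    continue
                wip = fit_two_by_two(table(ec, ev), "wip", "pm1")
                mle = fit_two_by_two(table(ec, ev), "logistic", "pm1")
                assert abs(wip.params["treatment"]) <= \
                    abs(mle.params["treatment"]) + 1e-10

    def test_em_fixed_point_self_consistency(self):
        # at convergence the estimate solves the ridge-penalized score
        # equation with prior variances (beta^2 + V + s^2)/2
        from scipy.special import expit

        data = table(3, 1).expand("pm1")
        model = PenalizedLogit(data, "cauchy")
        fit = model.fit()
        beta = fit.params.to_numpy()
        V = np.diag(fit.cov_params.to_numpy())
        sigma2 = (beta ** 2 + V + model.prior_scales ** 2) / 2.0
        X, y = data.exog, data.outcome
        score = X.T @ (y - expit(X @ beta)) - beta / sigma2
        assert np.max(np.abs(score)) < 1e-5

    def test_inner_ridge_objective_ascends(self):
        fit = fit_two_by_two(table(8, 0), "wip", "pm1")
        for inner in fit.objective_trace:
            assert np.all(np.diff(np.asarray(inner)) >= -1e-8)


class TestCodingCovariance:
    @pytest.mark.parametrize("method", ["logistic", "firth"])
    def test_exact_halving_for_likelihood_fits(self, method):
        for ec, ev in [(2, 3), (3, 1), (9, 2), (4, 6)]:
            f01 = fit_two_by_two(table(ec, ev), method, "01")
            fpm = fit_two_by_two(table(ec, ev), method, "pm1")
            assert f01.params["treatment"] == pytest.approx(
                2 * fpm.params["treatment"], abs=1e-6)
            assert f01.bse["treatment"] == pytest.approx(
                2 * fpm.bse["treatment"], abs=1e-6)

    def test_wip_approximately_equivariant(self):
        # the prior rescaling makes the slope prior coding-equivariant,
        # but the fixed intercept prior couples weakly to the slope
        for ec, ev in [(2, 3), (3, 1), (9, 2)]:
            f01 = fit_two_by_two(table(ec, ev), "wip", "01")
            fpm = fit_two_by_two(table(ec, ev), "wip", "pm1")
            assert f01.params["treatment"] == pytest.approx(
                2 * fpm.params["treatment"], rel=0.03)


class TestGaussian:
    def test_two_group_coefficient_is_mean_difference(self):
        rng = np.random.default_rng(5)
        z = np.r_[np.zeros(30), np.ones(40)]
        y = rng.normal(2.0 + 1.3 * z, 1.0)
        fit = fit_linear_gaussian(RegressionData(
            y, pd.DataFrame({"c": np.ones(70), "z": z})))
        assert fit.params["z"] == pytest.approx(
            y[z == 1].mean() - y[z == 0].mean(), abs=1e-10)

    def test_perfect_fit_recovers_identity(self):
        x = np.arange(10.0)
        fit = fit_linear_gaussian(RegressionData(
            x, pd.DataFrame({"c": np.ones(10), "x": x})))
        assert fit.params["x"] == pytest.approx(1.0, abs=1e-12)
        assert fit.params["c"] == pytest.approx(0.0, abs=1e-10)

    def test_parameter_recovery_large_sample(self):
        rng = np.random.default_rng(11)
        z = np.r_[np.zeros(2500), np.ones(2500)]
        y = rng.normal(1.0 + 1.5 * z, 0.8)
        fit = fit_linear_gaussian(RegressionData(
            y, pd.DataFrame({"c": np.ones(5000), "z": z})))
        assert abs(fit.params["z"] - 1.5) < 3 * fit.bse["z"]


class TestWald:
    def test_normal_quantile_examples(self):
        fit = fit_two_by_two(table(2, 3), "logistic", "pm1")
        fake = fit  # reuse container shape via direct computation
        z, p = wald_test(fake, "treatment", null_value=fit.params["treatment"])
        assert p == pytest.approx(1.0)
        # z = 1.96 should give p ~ 0.05
        target = fit.params["treatment"] - 1.96 * fit.bse["treatment"]
        _, p196 = wald_test(fit, "treatment", null_value=target)
        assert p196 == pytest.approx(0.0500, abs=5e-4)

    def test_unknown_coefficient_and_bad_se(self):
        fit = fit_two_by_two(table(2, 3), "logistic", "pm1")
        with pytest.raises(KeyError):
            wald_test(fit, "nonexistent")
        bad = fit_two_by_two(table(0, 0), "firth", "pm1")
        bad.cov_params.loc["treatment", "treatment"] = 0.0
        with pytest.raises(ValueError, match="standard error"):
            wald_test(bad, "treatment")


class TestTwoByTwoDispatch:
    def test_matches_direct_fit_on_expanded_data(self):
        t = table(3, 1)
        for method, fn in [("logistic", fit_logistic_mle),
                           ("firth", fit_firth), ("wip", fit_cauchy_wip)]:
            via_table = fit_two_by_two(t, method, "pm1")
            direct = fn(t.expand("pm1"))
            np.testing.assert_allclose(via_table.params.to_numpy(),
                                       direct.params.to_numpy(), atol=1e-12)

    def test_unknown_method_or_coding(self):
        with pytest.raises(ValueError, match="method"):
            fit_two_by_two(table(1, 1), "ridge")
        with pytest.raises(ValueError, match="coding"):
            fit_two_by_two(table(1, 1), "firth", "2x")

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(10, 10, 11, 0)
        with pytest.raises(ValueError):
            TwoByTwo(10, 10, -1, 0)
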