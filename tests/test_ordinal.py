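"""Ordered probit and binary probit: likelihood values, fitting, and the
statsmodels cross-check."""

import numpy as np
import pytest
from scipy.stats import norm

from ordtreat import (
    fit_ordered_probit,
    fit_probit,
    oprobit_loglik,
    predict_category_probs,
)


def _sim_oprobit(n, beta, mu, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(beta)))
    ystar = X @ np.asarray(beta) + rng.standard_normal(n)
    y = 1 + np.searchsorted(np.asarray(mu), ystar)
    return y, X


class TestLoglik:
    def test_symmetric_cutpoints_give_quarter_probabilities(self):
        mu = norm.ppf([0.25, 0.5, 0.75])
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = rng.integers(1, 5, size=40)
        ll = oprobit_loglik(np.zeros(3), mu, y, X)
        assert ll == pytest.approx(40 * np.log(0.25), rel=1e-12)

    def test_top_category_contribution(self):
        mu = np.array([-1.0, 0.2, 1.3])
        X = np.array([[0.7]])
        beta = np.array([0.9])
        ll = oprobit_loglik(beta, mu, np.array([4]), X)
        assert ll == pytest.approx(np.log(1 - norm.cdf(1.3 - 0.63)), rel=1e-12)

    def test_nonincreasing_cutpoints_rejected(self):
        with pytest.raises(ValueError):
            oprobit_loglik([0.0], [0.5, 0.5, 1.0], np.array([1]), np.array([[1.0]]))

    def test_matches_statsmodels_ordered_model(self):
        """Independent per-row probability computation via statsmodels."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        y, X = _sim_oprobit(300, [0.5, -0.3], [-0.8, 0.4, 1.2], seed=3)
        mod = OrderedModel(y, X, distr="probit")
        beta = np.array([0.45, -0.25])
        mu = np.array([-0.7, 0.3, 1.1])
        sm_params = np.concatenate([beta, [mu[0]], np.log(np.diff(mu))])
        assert oprobit_loglik(beta, mu, y, X) == pytest.approx(
            mod.loglike(sm_params), rel=1e-10
        )


class TestFitOrderedProbit:
    def test_parameter_recovery_within_three_se(self):
        beta = [0.5, -0.4]
        mu = [-1.2, 0.3, 1.1]
        y, X = _sim_oprobit(20000, beta, mu, seed=11)
        fit = fit_ordered_probit(y, X)
        assert fit.converged
        assert np.all(np.diff(fit.mu) > 0)
        est = np.concatenate([fit.beta, fit.mu])
        truth = np.concatenate([beta, mu])
        assert np.all(np.abs(est - truth) < 3 * fit.se)

    def test_agrees_with_statsmodels_fit(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        y, X = _sim_oprobit(2000, [0.6], [-0.5, 0.5, 1.5], seed=21)
        fit = fit_ordered_probit(y, X)
        sm_fit = OrderedModel(y, X, distr="probit").fit(method="bfgs", disp=0)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-5)
        assert fit.beta[0] == pytest.approx(sm_fit.params[0], abs=1e-4)

    def test_null_model_betas_near_zero(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(5000, 2))
        y = rng.integers(1, 5, size=5000)  # independent of X
        fit = fit_ordered_probit(y, X)
        assert np.all(np.abs(fit.beta) < 3 * fit.se[:2])

    def test_scale_equivariance(self):
        y, X = _sim_oprobit(1000, [0.5, -0.4], [-1, 0, 1], seed=4)
        fit1 = fit_ordered_probit(y, X, compute_vcov=False)
        X2 = X.copy()
        X2[:, 0] *= 10
        fit2 = fit_ordered_probit(y, X2, compute_vcov=False)
        assert fit2.beta[0] == pytest.approx(fit1.beta[0] / 10, rel=1e-4)
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-6)

    def test_binary_collapse_equals_probit(self):
        """A 2-category ordered probit is a binary probit with the intercept
        absorbed into the single cutpoint (shared code path)."""
        y, X = _sim_oprobit(3000, [0.7], [0.2], seed=6)
        fit2 = fit_ordered_probit(y, X)
        pro = fit_probit((y == 2).astype(int), X)
        assert fit2.beta[0] == pytest.approx(pro.gamma[1], abs=1e-5)
        assert fit2.mu[0] == pytest.approx(-pro.gamma[0], abs=1e-5)
        assert fit2.loglik == pytest.approx(pro.loglik, abs=1e-6)

    def test_rank_deficiency_names_column(self):
        y, X = _sim_oprobit(200, [0.5], [0.0], seed=7)
        Xdup = np.column_stack([X, X[:, 0]])
        with pytest.raises(ValueError, match="collinear"):
            fit_ordered_probit(y, Xdup, names=["a", "a_copy"])

    def test_unobserved_category_rejected(self):
        y, X = _sim_oprobit(200, [0.5], [-1.0, 0.0, 1.0], seed=7)
        y = np.where(y == 2, 3, y)
        with pytest.raises(ValueError, match="category"):
            fit_ordered_probit(y, X)


class TestFitProbit:
    def test_null_model_intercept_matches_share(self):
        rng = np.random.default_rng(9)
        Z = rng.normal(size=(6000, 2))
        t = (rng.random(6000) < 0.3).astype(int)  # unrelated to Z
        fit = fit_probit(t, Z)
        assert fit.gamma[0] == pytest.approx(norm.ppf(t.mean()), abs=0.05)
        assert np.all(np.abs(fit.gamma[1:]) < 3 * fit.se[1:])

    def test_recovery_within_three_se(self):
        rng = np.random.default_rng(10)
        Z = rng.normal(size=(20000, 2))
        gamma = np.array([-0.4, 0.6, -0.5])
        t = (gamma[0] + Z @ gamma[1:] + rng.standard_normal(20000) > 0).astype(int)
        fit = fit_probit(t, Z)
        assert np.all(np.abs(fit.gamma - gamma) < 3 * fit.se)

    def test_perfect_separation_reported(self):
        d = np.repeat([0, 1], 50)
        Z = d[:, None].astype(float)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = fit_probit(d, Z)
                assert not fit.converged
            except RuntimeError:
                pass  # explicit separation error is also acceptable


class TestPredictCategoryProbs:
    def test_rows_sum_to_one(self, compact_design):
        d, _ = compact_design
        X = np.column_stack([d.X.to_numpy(), d.t])
        fit = fit_ordered_probit(d.y, X, compute_vcov=False)
        P = predict_category_probs(fit, X)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(P >= 0)

    def test_zero_beta_gives_identical_rows(self):
        from ordtreat.ordinal import OrderedProbitFit

        fit = OrderedProbitFit(
            beta=np.zeros(2),
            mu=np.array([-1.0, 0.0, 1.0]),
            loglik=0.0,
            vcov=np.eye(5),
            converged=True,
        )
        P = predict_category_probs(fit, np.random.default_rng(0).normal(size=(6, 2)))
        assert np.allclose(P, P[0])

    def test_stochastic_dominance_in_index(self):
        from ordtreat.ordinal import OrderedProbitFit

        fit = OrderedProbitFit(
            beta=np.array([1.0]),
            mu=np.array([-1.0, 0.2, 1.4]),
            loglik=0.0,
            vcov=np.eye(4),
            converged=True,
        )
        grid = np.linspace(-2, 2, 21)[:, None]
        P = predict_category_probs(fit, grid)
        cum = P.cumsum(axis=1)
        # increasing index shifts mass upward: CDF at each category falls
        assert np.all(np.diff(cum[:, :3], axis=0) <= 1e-12)

    def test_column_mismatch_rejected(self, compact_design):
        d, _ = compact_design
        X = np.column_stack([d.X.to_numpy(), d.t])
        fit = fit_ordered_probit(d.y, X, compute_vcov=False)
        with pytest.raises(ValueError, match="columns"):
            predict_category_probs(fit, d.X.to_numpy())
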