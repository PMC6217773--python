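"""The joint endogenous-treatment/ordered-outcome estimator: likelihood
identities, oracle agreement, gradient correctness, parameter recovery and
the LR test of error independence."""

import warnings

import numpy as np
import pytest
from scipy.optimize import approx_fprime
from scipy.stats import norm

from ordtreat import (
    ETOPParams,
    etop_cell_probs,
    etop_loglik_closed,
    etop_loglik_simulated,
    fit_etop,
    fit_ordered_probit,
    fit_probit,
    lr_test_independence,
    oprobit_loglik,
)
from ordtreat.etop import ETOPFit, _closed_negll_grad


def random_point(rng, n=150, p_x=2):
    """A random parameter point with data generated from it, so realized
    cells carry non-negligible probability."""
    X = rng.normal(size=(n, p_x))
    Z = np.column_stack([X, rng.normal(size=n)])
    p = ETOPParams(
        gamma=rng.normal(scale=0.5, size=p_x + 2),
        beta=rng.normal(scale=0.5, size=p_x),
        delta=rng.normal(scale=0.7),
        mu=np.sort(rng.normal(scale=1.2, size=3)),
        rho=rng.uniform(-0.8, 0.8),
    )
    c = p.gamma[0] + Z @ p.gamma[1:]
    L = np.linalg.cholesky([[1, p.rho], [p.rho, 1]])
    e = rng.standard_normal((n, 2)) @ L.T
    t = (c + e[:, 0] > 0).astype(int)
    y = 1 + np.searchsorted(p.mu, X @ p.beta + p.delta * t + e[:, 1])
    return p, y, t, X, Z


class TestClosedForm:
    def test_rho_zero_factorizes_exactly(self):
        rng = np.random.default_rng(2)
        p, y, t, X, Z = random_point(rng)
        p0 = ETOPParams(p.gamma, p.beta, p.delta, p.mu, 0.0)
        llj = etop_loglik_closed(p0, y, t, X, Z)
        c = p0.gamma[0] + Z @ p0.gamma[1:]
        llp = float(np.sum(np.log(np.where(t == 1, norm.cdf(c), norm.cdf(-c)))))
        llo = oprobit_loglik(
            np.concatenate([p0.beta, [p0.delta]]), p0.mu, y, np.column_stack([X, t])
        )
        assert llj == pytest.approx(llp + llo, abs=1e-10)

    def test_cell_probabilities_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p, y, t, X, Z = random_point(rng, n=40)
            cp = etop_cell_probs(p, X, Z)
            np.testing.assert_allclose(cp.sum(axis=(1, 2)), 1.0, atol=1e-10)
            assert np.all(cp >= -1e-14)

    def test_matches_monte_carlo_cell_integration(self):
        """Brute-force 2-D Monte Carlo over the (v, eps) regions."""
        p = ETOPParams(
            gamma=[0.2, 0.4], beta=[0.3], delta=0.8, mu=[-1.0, 0.4, 1.5], rho=-0.5
        )
        x = np.array([[0.6]])
        z = np.array([[-0.3]])
        n_mc = 1_000_000
        rng = np.random.default_rng(99)
        L = np.linalg.cholesky([[1, p.rho], [p.rho, 1]])
        e = rng.standard_normal((n_mc, 2)) @ L.T
        c = p.gamma[0] + z[0, 0] * p.gamma[1]
        t_mc = (c + e[:, 0] > 0).astype(int)
        ystar = x[0, 0] * p.beta[0] + p.delta * t_mc + e[:, 1]
        y_mc = 1 + np.searchsorted(p.mu, ystar)
        cp = etop_cell_probs(p, x, z)[0]
        for tt in (0, 1):
            for yy in (1, 2, 3, 4):
                emp = np.mean((t_mc == tt) & (y_mc == yy))
                assert cp[tt, yy - 1] == pytest.approx(emp, abs=1.5e-3)

    def test_nonpositive_contribution_raises_with_row(self):
        # impossible observation under a near-degenerate parameter point is
        # floored, not negative; exercising the guard requires a bogus prob,
        # so check the flooring path instead: loglik stays finite
        p = ETOPParams(gamma=[30.0, 0.0], beta=[0.0], delta=0.0, mu=[-1, 0, 1], rho=0.5)
        ll = etop_loglik_closed(
            p, np.array([1]), np.array([0]), np.array([[0.0]]), np.array([[0.0]])
        )
        assert np.isfinite(ll)


class TestSimulatedLikelihood:
    def test_gauss_hermite_agrees_with_closed_form(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            p, y, t, X, Z = random_point(rng)
            llc = etop_loglik_closed(p, y, t, X, Z)
            llg = etop_loglik_simulated(p, y, t, X, Z, n_draws=64, scheme="gauss_hermite")
            assert llg == pytest.approx(llc, rel=1e-6)

    def test_halton_agrees_with_closed_form(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            p, y, t, X, Z = random_point(rng)
            llc = etop_loglik_closed(p, y, t, X, Z)
            llh = etop_loglik_simulated(p, y, t, X, Z, n_draws=500, scheme="halton")
            assert llh == pytest.approx(llc, rel=1e-3)

    def test_rho_zero_independent_of_draw_count(self):
        rng = np.random.default_rng(7)
        p, y, t, X, Z = random_point(rng)
        p0 = ETOPParams(p.gamma, p.beta, p.delta, p.mu, 0.0)
        llc = etop_loglik_closed(p0, y, t, X, Z)
        for nd in (16, 64):
            ll = etop_loglik_simulated(p0, y, t, X, Z, n_draws=nd, scheme="gauss_hermite")
            assert ll == pytest.approx(llc, abs=1e-10)

    def test_invalid_scheme_and_draws_rejected(self):
        rng = np.random.default_rng(8)
        p, y, t, X, Z = random_point(rng, n=20)
        with pytest.raises(ValueError, match="scheme"):
            etop_loglik_simulated(p, y, t, X, Z, scheme="sobol")
        with pytest.raises(ValueError, match="n_draws"):
            etop_loglik_simulated(p, y, t, X, Z, n_draws=4)

    def test_deterministic_given_scheme(self):
        rng = np.random.default_rng(9)
        p, y, t, X, Z = random_point(rng, n=50)
        a = etop_loglik_simulated(p, y, t, X, Z, n_draws=100, scheme="halton")
        b = etop_loglik_simulated(p, y, t, X, Z, n_draws=100, scheme="halton")
        assert a == b


def test_analytic_gradient_matches_finite_differences():
    rng = np.random.default_rng(10)
    p, y, t, X, Z = random_point(rng, n=120)
    theta = p.pack()
    p_z, p_x, k_cut = Z.shape[1], X.shape[1], len(p.mu)
    f = lambda th: _closed_negll_grad(th, y, t, X, Z, p_z, p_x, k_cut)[0]
    g_num = approx_fprime(theta, f, 1e-6)
    g_ana = _closed_negll_grad(theta, y, t, X, Z, p_z, p_x, k_cut)[1]
    np.testing.assert_allclose(g_ana, g_num, rtol=1e-4, atol=1e-4)


class TestFitEtop:
    def test_recovery_within_three_se(self, compact_design):
        d, tp = compact_design  # rho=-0.5, delta=1.0, n=4000
        fit = fit_etop(d.y, d.t, d.X, d.Z)
        assert fit.converged
        i_d = fit.names.index("treatment(delta)")
        i_r = fit.names.index("rho")
        assert abs(fit.delta - tp.delta) < 3 * fit.se[i_d]
        assert abs(fit.rho - tp.rho) < 3 * fit.se[i_r]

    def test_rho_zero_truth_matches_naive(self):
        from tests_helpers import make_compact_design

        d, tp = make_compact_design(6000, rho=0.0, delta=1.0, seed=14)
        fit = fit_etop(d.y, d.t, d.X, d.Z)
        opr = fit_ordered_probit(
            d.y, np.column_stack([d.X.to_numpy(), d.t]), compute_vcov=False
        )
        i_d = fit.names.index("treatment(delta)")
        assert abs(fit.delta - opr.beta[-1]) < 3 * fit.se[i_d]

    def test_negative_rho_attenuates_naive_estimate(self, compact_design):
        """With rho < 0 and delta > 0 the naive ordered probit understates
        the treatment effect (the endogeneity-bias contrast)."""
        d, tp = compact_design
        fit = fit_etop(d.y, d.t, d.X, d.Z, compute_vcov=False)
        opr = fit_ordered_probit(
            d.y, np.column_stack([d.X.to_numpy(), d.t]), compute_vcov=False
        )
        assert opr.beta[-1] < fit.delta

    def test_no_exclusion_restriction_refused(self, compact_design):
        d, _ = compact_design
        with pytest.raises(ValueError, match="exclusion"):
            fit_etop(d.y, d.t, d.X, d.X)

    def test_weak_identification_warns(self):
        from tests_helpers import make_weakiv_design

        d = make_weakiv_design(3000, seed=15)
        with pytest.warns(UserWarning, match="weak identification"):
            fit_etop(d.y, d.t, d.X, d.Z, maxiter=5, compute_vcov=False)


class TestLRTest:
    def _triple(self, d):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pro = fit_probit(d.t, d.Z, names=list(d.Z.columns))
            opr = fit_ordered_probit(
                d.y,
                np.column_stack([d.X.to_numpy(), d.t]),
                compute_vcov=False,
            )
            joint = fit_etop(d.y, d.t, d.X, d.Z, compute_vcov=False)
        return joint, pro, opr

    def test_restricted_model_consistency(self, compact_design):
        """The joint likelihood at the separate fits' estimates with rho=0
        equals the sum of their maximized log-likelihoods."""
        d, _ = compact_design
        joint, pro, opr = self._triple(d)
        restricted = ETOPParams(
            gamma=pro.gamma,
            beta=opr.beta[:-1],
            delta=float(opr.beta[-1]),
            mu=opr.mu,
            rho=0.0,
        )
        ll = etop_loglik_closed(restricted, d.y, d.t, d.X.to_numpy(), d.Z.to_numpy())
        assert ll == pytest.approx(pro.loglik + opr.loglik, abs=1e-8)

    def test_statistic_positive_and_significant_under_strong_rho(
        self, compact_design
    ):
        d, _ = compact_design  # rho=-0.5 truth at n=4000
        joint, pro, opr = self._triple(d)
        lr = lr_test_independence(joint, pro, opr)
        assert lr.df == 1
        assert lr.statistic > 0
        assert lr.p_value < 0.05

    def test_rho_fixed_at_zero_gives_zero_statistic(self, compact_design):
        d, _ = compact_design
        joint, pro, opr = self._triple(d)
        restricted = ETOPParams(
            gamma=pro.gamma, beta=opr.beta[:-1], delta=float(opr.beta[-1]),
            mu=opr.mu, rho=0.0,
        )
        forced = ETOPFit(
            params=restricted,
            loglik=etop_loglik_closed(
                restricted, d.y, d.t, d.X.to_numpy(), d.Z.to_numpy()
            ),
            vcov=np.eye(1),
            converged=True,
            n=joint.n,
        )
        lr = lr_test_independence(forced, pro, opr)
        assert lr.statistic == pytest.approx(0, abs=1e-6)

    def test_mismatched_samples_rejected(self, compact_design):
        d, _ = compact_design
        joint, pro, opr = self._triple(d)
        pro.n -= 1
        with pytest.raises(ValueError, match="sample sizes"):
            lr_test_independence(joint, pro, opr)


def test_optimizer_reaches_local_maximum(compact_design):
    """Perturbing any single parameter from the optimum lowers the joint
    log-likelihood."""
    d, _ = compact_design
    fit = fit_etop(d.y, d.t, d.X, d.Z, compute_vcov=False)
    ll_hat = fit.loglik
    X, Z = d.X.to_numpy(), d.Z.to_numpy()
    p = fit.params
    rng = np.random.default_rng(0)
    for _ in range(5):
        theta = p.pack()
        theta[rng.integers(len(theta))] += rng.choice([-0.05, 0.05])
        pert = ETOPParams.unpack(theta, Z.shape[1], X.shape[1], len(p.mu))
        assert etop_loglik_closed(pert, d.y, d.t, X, Z) <= ll_hat + 1e-6
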