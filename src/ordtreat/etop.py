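"""Endogenous treatment effects model with an ordered outcome.

Model.  A binary treatment T (smoking) and an ordinal outcome Y (BMI
class, 1..K) are driven by two latent indices with correlated standard
normal errors:

    T* = gamma0 + z'gamma + v,          T = 1[T* > 0]
    Y* = x'beta + delta*T + eps,        Y = j  iff  mu_{j-1} < Y* <= mu_j

with (v, eps) bivariate standard normal, corr(v, eps) = rho.  z strictly
extends x by at least one excluded variable (the instrument), which
identifies delta separately from rho.  Both error variances are fixed at
1; the outcome equation has no intercept (the cutpoints absorb location).

The likelihood has a closed form in the bivariate normal CDF.  With
c = gamma0 + z'gamma and a_j = mu_j - x'beta - delta*t:

    P(T=0, Y=j) = Phi2(a_j, -c; rho) - Phi2(a_{j-1}, -c; rho)
    P(T=1, Y=j) = [Phi(a_j) - Phi2(a_j, -c; rho)]
                - [Phi(a_{j-1}) - Phi2(a_{j-1}, -c; rho)]

A simulated version integrates a shared latent factor by Gauss-Hermite
quadrature or Halton quasi-Monte Carlo; it exists to cross-validate the
closed form and is interchangeable with it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import ndtr, roots_hermitenorm
from scipy.stats import chi2, norm, qmc

from ._bvn import bvn_cdf, bvn_pdf
from .ordinal import (
    OrderedProbitFit,
    ProbitFit,
    _category_bounds,
    _check_rank,
    _cutpoints,
    _mu_jacobian,
    _numeric_hessian,
    _theta_from_cutpoints,
    fit_ordered_probit,
    fit_probit,
)

_PROB_FLOOR = 1e-300


@dataclass
class ETOPParams:
    """Full parameter vector of the joint model."""

    gamma: np.ndarray  # treatment equation, intercept first (len p_z + 1)
    beta: np.ndarray  # outcome equation (len p_x, no intercept)
    delta: float  # treatment effect on the latent outcome
    mu: np.ndarray  # strictly increasing cutpoints (len K - 1)
    rho: float  # corr(v, eps), in (-1, 1)

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if np.any(np.diff(self.mu) <= 0):
            raise ValueError("cutpoints must be strictly increasing")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [
                self.gamma,
                self.beta,
                [self.delta],
                _theta_from_cutpoints(self.mu),
                [np.arctanh(self.rho)],
            ]
        )

    @classmethod
    def unpack(cls, theta: np.ndarray, p_z: int, p_x: int, k_cut: int):
        i = 0
        gamma = theta[i : i + p_z + 1]
        i += p_z + 1
        beta = theta[i : i + p_x]
        i += p_x
        delta = float(theta[i])
        i += 1
        mu = _cutpoints(theta[i : i + k_cut])
        i += k_cut
        rho = float(np.tanh(theta[i]))
        return cls(gamma=gamma, beta=beta, delta=delta, mu=mu, rho=rho)


@dataclass
class ETOPFit:
    params: ETOPParams
    loglik: float
    vcov: np.ndarray  # on the (gamma, beta, delta, mu, rho) scale
    converged: bool
    method: str = "closed_form"
    n_draws: int | None = None
    seed: int | None = None
    names: list[str] = field(default_factory=list)
    n: int = 0
    grad_norm: float = np.nan

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    @property
    def delta(self) -> float:
        return self.params.delta

    @property
    def rho(self) -> float:
        return self.params.rho


@dataclass
class LRTestResult:
    statistic: float
    df: int
    p_value: float


def _indices(params: ETOPParams, t, X, Z):
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if X.shape[1] != len(params.beta):
        raise ValueError("X has wrong number of columns for beta")
    if Z.shape[1] != len(params.gamma) - 1:
        raise ValueError("Z has wrong number of columns for gamma")
    c = params.gamma[0] + Z @ params.gamma[1:]
    xb = X @ params.beta + params.delta * np.asarray(t, dtype=float)
    return c, xb


def etop_cell_probs(params: ETOPParams, X, Z) -> np.ndarray:
    """n x 2 x K array of P(T=t, Y=j | x, z); cells sum to 1 per row."""
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n = X.shape[0]
    k = len(params.mu) + 1
    out = np.empty((n, 2, k))
    c = params.gamma[0] + Z @ params.gamma[1:]
    ext = np.concatenate(([-np.inf], params.mu, [np.inf]))
    for t in (0, 1):
        a = ext[None, :] - (X @ params.beta + params.delta * t)[:, None]
        F = bvn_cdf(a, -c[:, None], params.rho)  # n x (k+1)
        if t == 0:
            out[:, 0, :] = np.diff(F, axis=1)
        else:
            out[:, 1, :] = np.diff(ndtr(a) - F, axis=1)
    return out


def etop_loglik_closed(params: ETOPParams, y, t, X, Z) -> float:
    """Exact joint log-likelihood via the bivariate normal CDF."""
    y = np.asarray(y, dtype=int)
    t = np.asarray(t, dtype=int)
    c, xb = _indices(params, t, X, Z)
    up, lo = _category_bounds(params.mu, y, xb)
    F_up = bvn_cdf(up, -c, params.rho)
    F_lo = bvn_cdf(lo, -c, params.rho)
    p0 = F_up - F_lo
    p1 = (ndtr(up) - F_up) - (ndtr(lo) - F_lo)
    p = np.where(t == 0, p0, p1)
    bad = p <= -1e-8
    if bad.any():
        raise FloatingPointError(
            f"non-positive likelihood contribution at rows {np.where(bad)[0][:5]}"
        )
    return float(np.sum(np.log(np.maximum(p, _PROB_FLOOR))))


def _closed_negll_grad(theta, y, t, X, Z, p_z, p_x, k_cut):
    """Negative log-likelihood and analytic gradient on the packed scale."""
    params = ETOPParams.unpack(theta, p_z, p_x, k_cut)
    rho = params.rho
    c, xb = _indices(params, t, X, Z)
    up, lo = _category_bounds(params.mu, y, xb)
    F_up = bvn_cdf(up, -c, rho)
    F_lo = bvn_cdf(lo, -c, rho)
    phi_up = np.where(np.isfinite(up), norm.pdf(up), 0.0)
    phi_lo = np.where(np.isfinite(lo), norm.pdf(lo), 0.0)
    t = np.asarray(t, dtype=int)
    sgn = 2.0 * t - 1.0

    p0 = F_up - F_lo
    p1 = (ndtr(up) - F_up) - (ndtr(lo) - F_lo)
    p = np.maximum(np.where(t == 0, p0, p1), _PROB_FLOOR)
    ll = float(np.sum(np.log(p)))

    s = np.sqrt(1.0 - rho * rho)
    # partials of Phi2(h, k; rho): dh -> phi(h) Phi((k - rho h)/s), dk symmetric
    with np.errstate(invalid="ignore"):
        Fh_up = phi_up * ndtr(np.where(np.isfinite(up), (-c - rho * up) / s, 0.0))
        Fh_lo = phi_lo * ndtr(np.where(np.isfinite(lo), (-c - rho * lo) / s, 0.0))
        Fk_up = norm.pdf(c) * ndtr(
            np.where(np.isfinite(up), (up + rho * c) / s, np.sign(up) * np.inf)
        )
        Fk_lo = norm.pdf(c) * ndtr(
            np.where(np.isfinite(lo), (lo + rho * c) / s, np.sign(lo) * np.inf)
        )
    f2_up = bvn_pdf(up, -c, rho)
    f2_lo = bvn_pdf(lo, -c, rho)

    # dP/d(upper bound a_y), dP/d(lower bound a_{y-1}), dP/dc, dP/drho
    dP_up = np.where(t == 0, Fh_up, phi_up - Fh_up)
    dP_lo = np.where(t == 0, -Fh_lo, -(phi_lo - Fh_lo))
    dP_dc = sgn * (Fk_up - Fk_lo)
    dP_drho = -sgn * (f2_up - f2_lo)

    inv_p = 1.0 / p
    w_idx = (dP_up + dP_lo) * inv_p  # d ll_i / d a (both bounds move with -x'b)
    Zc = np.column_stack([np.ones(len(t)), np.asarray(Z, dtype=float)])
    g_gamma = Zc.T @ (dP_dc * inv_p)
    Xa = np.asarray(X, dtype=float)
    g_beta = -(Xa.T @ w_idx)
    g_delta = -float(np.sum(w_idx * t))
    g_mu = np.zeros(k_cut)
    y = np.asarray(y, dtype=int)
    for j in range(1, k_cut + 1):
        sel_up = y == j
        sel_lo = y == j + 1
        g_mu[j - 1] = np.sum(dP_up[sel_up] * inv_p[sel_up]) + np.sum(
            dP_lo[sel_lo] * inv_p[sel_lo]
        )
    g_rho = float(np.sum(dP_drho * inv_p))

    i_mu = p_z + 1 + p_x + 1
    g_theta_mu = _mu_jacobian(theta[i_mu : i_mu + k_cut]).T @ g_mu
    g_w = (1.0 - rho * rho) * g_rho  # atanh scale
    grad = np.concatenate([g_gamma, g_beta, [g_delta], g_theta_mu, [g_w]])
    return -ll, -grad


def _factor_loadings(rho: float) -> tuple[float, float]:
    """Map rho to symmetric factor loadings (lam_T, lam_Y).

    v = (lam_T eta + u_T)/sqrt(1 + lam_T^2), likewise for eps, with a
    shared standard normal factor eta; corr(v, eps) then equals
    sign(rho) lam^2/(1 + lam^2), which covers all rho in (-1, 1) with
    lam^2 = |rho|/(1 - |rho|).
    """
    lam = np.sqrt(abs(rho) / (1.0 - abs(rho)))
    return lam, np.sign(rho) * lam


def etop_loglik_simulated(
    params: ETOPParams,
    y,
    t,
    X,
    Z,
    n_draws: int = 500,
    seed: int = 0,
    scheme: str = "halton",
) -> float:
    """Joint log-likelihood by latent-factor integration.

    Conditional on the factor eta the two equations are independent:
    P(T, Y | eta) is a probit term times an ordered-probit term with
    factor-shifted indices.  The eta integral is taken by Gauss-Hermite
    quadrature (``scheme='gauss_hermite'``) or by averaging over
    Phi-inverse-transformed Halton points (``scheme='halton'``,
    deterministic: unscrambled sequence, first point skipped).
    """
    if scheme not in ("halton", "gauss_hermite"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if n_draws < 16:
        raise ValueError("n_draws must be at least 16")
    y = np.asarray(y, dtype=int)
    t = np.asarray(t, dtype=int)
    c, _ = _indices(params, t, X, Z)
    xb = np.asarray(X, dtype=float) @ params.beta + params.delta * t

    lam_t, lam_y = _factor_loadings(params.rho)
    s_t = np.sqrt(1.0 + lam_t**2)
    s_y = np.sqrt(1.0 + lam_y**2)

    if scheme == "gauss_hermite":
        nodes, wts = roots_hermitenorm(n_draws)
        wts = wts / np.sqrt(2.0 * np.pi)
    else:
        # Halton points in probability space, turned into a quadrature rule:
        # cell weights from midpoint spacings, node at each cell's
        # truncated-normal centroid.  Orders of magnitude less bias than
        # equal-weight averaging at the same draw count (tails especially).
        h = qmc.Halton(d=1, scramble=False, seed=seed)
        h.fast_forward(1)
        u = np.sort(h.random(n_draws).ravel())
        edges = np.concatenate([[0.0], 0.5 * (u[1:] + u[:-1]), [1.0]])
        wts = np.diff(edges)
        zed = norm.ppf(edges)
        pdf = np.where(np.isfinite(zed), norm.pdf(np.clip(zed, -40, 40)), 0.0)
        nodes = (pdf[:-1] - pdf[1:]) / wts

    ext = np.concatenate(([-np.inf], params.mu, [np.inf]))
    up = ext[y] - xb
    lo = ext[y - 1] - xb

    # n x n_draws conditional probabilities
    eta = nodes[None, :]
    pt1 = ndtr(s_t * c[:, None] + lam_t * eta)
    pt = np.where((t == 1)[:, None], pt1, 1.0 - pt1)
    py = ndtr(
        np.where(np.isfinite(up), s_y * up, up)[:, None] - lam_y * eta
    ) - ndtr(np.where(np.isfinite(lo), s_y * lo, lo)[:, None] - lam_y * eta)
    p = (pt * py) @ wts
    return float(np.sum(np.log(np.maximum(p, _PROB_FLOOR))))


def fit_etop(
    y,
    t,
    X,
    Z,
    names_x=None,
    names_z=None,
    method: str = "closed",
    n_draws: int = 500,
    seed: int = 0,
    tol: float = 1e-7,
    maxiter: int = 500,
    start: ETOPParams | None = None,
    compute_vcov: bool = True,
    force: bool = False,
) -> ETOPFit:
    """Maximum likelihood for the joint model.

    ``method`` is 'closed' (exact, analytic gradients; the default),
    'halton' or 'ghq' (simulated/quadrature likelihood, numerical
    gradients).  Starting values come from separate probit and ordered
    probit fits with rho = 0 unless ``start`` is given.

    Raises unless Z strictly extends X (exclusion restriction) — pass
    ``force=True`` to fit anyway (identification then rests on
    functional form alone).
    """
    y = np.asarray(y, dtype=int)
    t = np.asarray(t, dtype=int)
    Xdf, Zdf = X, Z
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if names_x is None:
        names_x = list(getattr(Xdf, "columns", [f"x{i}" for i in range(X.shape[1])]))
    if names_z is None:
        names_z = list(getattr(Zdf, "columns", [f"z{i}" for i in range(Z.shape[1])]))

    x_cols = {tuple(X[:, i]) for i in range(X.shape[1])}
    extra = [i for i in range(Z.shape[1]) if tuple(Z[:, i]) not in x_cols]
    if not extra and not force:
        raise ValueError(
            "no exclusion restriction: every treatment-equation column also "
            "appears in the outcome equation; pass force=True to override"
        )
    _check_rank(np.column_stack([np.ones(len(t)), Z]), ["const"] + list(names_z))

    k = int(y.max())
    for arm in (0, 1):
        seen = np.unique(y[t == arm])
        if not np.array_equal(seen, np.arange(1, k + 1)):
            warnings.warn(
                f"not every outcome category observed in treatment arm {arm}",
                UserWarning,
                stacklevel=2,
            )
    k_cut = k - 1
    p_x, p_z = X.shape[1], Z.shape[1]

    if start is None:
        pro = fit_probit(t, Z, names=names_z)
        if extra:
            # first-stage Wald diagnostic on the exclusion restrictions
            # (rule of thumb: joint chi-square below ~10 per restriction
            # signals weak identification)
            idx = [i + 1 for i in extra]  # +1: intercept occupies slot 0
            g = pro.gamma[idx]
            V = pro.vcov[np.ix_(idx, idx)]
            try:
                wald = float(g @ np.linalg.solve(V, g))
            except np.linalg.LinAlgError:
                wald = np.nan
            if not np.isfinite(wald) or wald < 10.0 * len(extra):
                warnings.warn(
                    f"weak identification: first-stage Wald statistic for the "
                    f"exclusion restrictions is {wald:.2f} "
                    f"({len(extra)} restrictions)",
                    UserWarning,
                    stacklevel=2,
                )
        opr = fit_ordered_probit(
            y, np.column_stack([X, t]), names=list(names_x) + ["treatment"],
            compute_vcov=False,
        )
        start = ETOPParams(
            gamma=pro.gamma,
            beta=opr.beta[:-1],
            delta=float(opr.beta[-1]),
            mu=opr.mu,
            rho=0.0,
        )
    theta0 = start.pack()

    if method == "closed":
        obj = lambda th: _closed_negll_grad(th, y, t, X, Z, p_z, p_x, k_cut)
        res = optimize.minimize(
            obj, theta0, jac=True, method="BFGS",
            options={"gtol": tol, "maxiter": maxiter},
        )
    elif method in ("halton", "ghq"):
        scheme = "halton" if method == "halton" else "gauss_hermite"

        def negll(th):
            pp = ETOPParams.unpack(th, p_z, p_x, k_cut)
            return -etop_loglik_simulated(
                pp, y, t, X, Z, n_draws=n_draws, seed=seed, scheme=scheme
            )

        res = optimize.minimize(
            negll, theta0, method="BFGS",
            options={"gtol": max(tol, 1e-6), "maxiter": maxiter},
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    theta = res.x
    params = ETOPParams.unpack(theta, p_z, p_x, k_cut)
    ll = -float(res.fun)
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan

    n_par = len(theta)
    vcov = np.full((n_par, n_par), np.nan)
    if compute_vcov:
        grad_only = lambda th: _closed_negll_grad(th, y, t, X, Z, p_z, p_x, k_cut)[1]
        H = _numeric_hessian(grad_only, theta)
        try:
            vcov_theta = np.linalg.inv(H)
            J = np.eye(n_par)
            i_mu = p_z + 1 + p_x + 1
            J[i_mu : i_mu + k_cut, i_mu : i_mu + k_cut] = _mu_jacobian(
                theta[i_mu : i_mu + k_cut]
            )
            J[-1, -1] = 1.0 - params.rho**2  # d tanh(w) / d w
            vcov = J @ vcov_theta @ J.T
        except np.linalg.LinAlgError:
            pass

    method_name = {"closed": "closed_form", "halton": "simulated", "ghq": "quadrature"}[
        method
    ]
    names = (
        ["const"]
        + list(names_z)
        + list(names_x)
        + ["treatment(delta)"]
        + [f"mu_{j}" for j in range(1, k)]
        + ["rho"]
    )
    # scale-aware fallback: BFGS may stop on precision loss with a gradient
    # that is negligible relative to the log-likelihood magnitude (the
    # implied parameter step is ~grad/|ll| times the parameter scale)
    converged = bool(
        res.success
        or (np.isfinite(grad_norm) and grad_norm < 1e-5 * max(1.0, abs(ll)))
    )
    if not converged:
        warnings.warn("joint fit did not converge", UserWarning, stacklevel=2)
    return ETOPFit(
        params=params,
        loglik=ll,
        vcov=vcov,
        converged=converged,
        method=method_name,
        n_draws=n_draws if method != "closed" else None,
        seed=seed if method == "halton" else None,
        names=names,
        n=len(y),
        grad_norm=grad_norm,
    )


def lr_test_independence(
    joint: ETOPFit, probit: ProbitFit, oprobit: OrderedProbitFit
) -> LRTestResult:
    """Likelihood-ratio test of rho = 0 (independent treatment and outcome
    errors): 2*(l_joint - l_probit - l_oprobit) against chi-square(1).

    The restricted model factorizes into the separate probit (treatment)
    and ordered probit (outcome, including the treatment dummy) fits, so
    their maximized log-likelihoods sum to the restricted maximum.
    """
    if not (joint.n == probit.n == oprobit.n):
        raise ValueError(
            f"fits use different sample sizes: {joint.n}, {probit.n}, {oprobit.n}"
        )
    stat = 2.0 * (joint.loglik - probit.loglik - oprobit.loglik)
    if stat < 0:
        if stat < -1e-4:
            warnings.warn(
                f"LR statistic {stat:.3g} negative beyond tolerance; joint fit "
                "may not have converged",
                UserWarning,
                stacklevel=2,
            )
        stat = 0.0
    return LRTestResult(statistic=float(stat), df=1, p_value=float(chi2.sf(stat, 1)))
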