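"""Univariate ordered probit (maximum likelihood) and binary probit.

These are the no-endogeneity comparator for the joint treatment/outcome
model and the restricted models of the likelihood-ratio test of error
independence.

Parameterization: the ordered probit has no intercept — the latent error
SD is fixed at 1 and the location is absorbed into K-1 strictly
increasing cutpoints, optimized unconstrained as
(mu_1, log(mu_2 - mu_1), ..., log(mu_{K-1} - mu_{K-2})).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import linalg as sla
from scipy import optimize
from scipy.special import ndtr
from scipy.stats import norm

_PROB_FLOOR = 1e-300


def _check_rank(X: np.ndarray, names):
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify offending columns via pivoted QR diagonal
        _, R, piv = sla.qr(X, pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < 1e-8 * diag[0]]
        bad += [names[p] for p in piv[len(diag):]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _cutpoints(theta_mu: np.ndarray) -> np.ndarray:
    """Unconstrained (m1, log-gaps) -> strictly increasing cutpoints."""
    mu = np.empty(len(theta_mu))
    mu[0] = theta_mu[0]
    if len(theta_mu) > 1:
        mu[1:] = theta_mu[0] + np.cumsum(np.exp(theta_mu[1:]))
    return mu


def _theta_from_cutpoints(mu: np.ndarray) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    th = np.empty_like(mu)
    th[0] = mu[0]
    if len(mu) > 1:
        th[1:] = np.log(np.diff(mu))
    return th


def _mu_jacobian(theta_mu: np.ndarray) -> np.ndarray:
    """d mu / d theta_mu (lower triangular)."""
    k = len(theta_mu)
    J = np.zeros((k, k))
    J[:, 0] = 1.0
    for j in range(1, k):
        J[j:, j] = np.exp(theta_mu[j])
    return J


def _category_bounds(mu: np.ndarray, y: np.ndarray, index: np.ndarray):
    """Upper and lower latent thresholds (mu_y - index, mu_{y-1} - index)."""
    ext = np.concatenate(([-np.inf], mu, [np.inf]))
    return ext[y] - index, ext[y - 1] - index


def oprobit_loglik(beta, mu, y, X) -> float:
    """Ordered-probit log-likelihood; guards against log(0)."""
    beta = np.asarray(beta, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(np.diff(mu) <= 0):
        raise ValueError("cutpoints must be strictly increasing")
    y = np.asarray(y, dtype=int)
    X = np.asarray(X, dtype=float)
    up, lo = _category_bounds(mu, y, X @ beta)
    p = ndtr(up) - ndtr(lo)
    return float(np.sum(np.log(np.maximum(p, _PROB_FLOOR))))


def _oprobit_negll_grad(theta, y, X, k_cut):
    p_beta = theta[: X.shape[1]]
    mu = _cutpoints(theta[X.shape[1]:])
    up, lo = _category_bounds(mu, y, X @ p_beta)
    p = np.maximum(ndtr(up) - ndtr(lo), _PROB_FLOOR)
    ll = np.sum(np.log(p))

    phi_up = np.where(np.isfinite(up), norm.pdf(up), 0.0)
    phi_lo = np.where(np.isfinite(lo), norm.pdf(lo), 0.0)
    w = (phi_lo - phi_up) / p  # d ll_i / d (x_i' beta)
    g_beta = X.T @ w
    g_mu = np.zeros(k_cut)
    for j in range(1, k_cut + 1):
        g_mu[j - 1] = np.sum(phi_up[y == j] / p[y == j]) - np.sum(
            phi_lo[y == j + 1] / p[y == j + 1]
        )
    g_theta_mu = _mu_jacobian(theta[X.shape[1]:]).T @ g_mu
    return -ll, -np.concatenate([g_beta, g_theta_mu])


def _numeric_hessian(grad_fn, theta, eps=1e-5):
    k = len(theta)
    H = np.zeros((k, k))
    for i in range(k):
        step = np.zeros(k)
        step[i] = eps * max(1.0, abs(theta[i]))
        gp = grad_fn(theta + step)
        gm = grad_fn(theta - step)
        H[:, i] = (gp - gm) / (2 * step[i])
    return 0.5 * (H + H.T)


@dataclass
class OrderedProbitFit:
    beta: np.ndarray
    mu: np.ndarray
    loglik: float
    vcov: np.ndarray  # on the (beta, mu) scale
    converged: bool
    names: list[str] = field(default_factory=list)
    n: int = 0
    grad_norm: float = np.nan

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))


@dataclass
class ProbitFit:
    gamma: np.ndarray  # intercept first
    loglik: float
    vcov: np.ndarray
    converged: bool
    names: list[str] = field(default_factory=list)
    n: int = 0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))


def fit_ordered_probit(
    y,
    X,
    names=None,
    tol: float = 1e-8,
    maxiter: int = 500,
    compute_vcov: bool = True,
) -> OrderedProbitFit:
    """Maximum-likelihood ordered probit with analytic gradients.

    Starting values: beta = 0, cutpoints at the normal quantiles of the
    cumulative category shares.  Convergence requires gradient sup-norm
    below ``tol``.
    """
    y = np.asarray(y, dtype=int)
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    _check_rank(X, list(names))
    cats = np.unique(y)
    k = int(y.max())
    if not np.array_equal(cats, np.arange(1, k + 1)):
        raise ValueError(f"every category 1..{k} must be observed; saw {cats}")
    k_cut = k - 1

    shares = np.array([(y <= j).mean() for j in range(1, k)])
    mu0 = norm.ppf(shares)
    theta0 = np.concatenate([np.zeros(X.shape[1]), _theta_from_cutpoints(mu0)])

    res = optimize.minimize(
        _oprobit_negll_grad,
        theta0,
        args=(y, X, k_cut),
        jac=True,
        method="BFGS",
        options={"gtol": tol, "maxiter": maxiter},
    )
    theta = res.x
    grad_norm = float(np.max(np.abs(res.jac)))
    beta = theta[: X.shape[1]]
    mu = _cutpoints(theta[X.shape[1]:])
    ll = -float(res.fun)

    vcov = np.full((len(theta), len(theta)), np.nan)
    if compute_vcov:
        grad_only = lambda th: _oprobit_negll_grad(th, y, X, k_cut)[1]
        H = _numeric_hessian(grad_only, theta)  # Hessian of -ll
        try:
            vcov_theta = np.linalg.inv(H)
            J = np.eye(len(theta))
            J[X.shape[1]:, X.shape[1]:] = _mu_jacobian(theta[X.shape[1]:])
            vcov = J @ vcov_theta @ J.T
        except np.linalg.LinAlgError:
            pass

    return OrderedProbitFit(
        beta=beta,
        mu=mu,
        loglik=ll,
        vcov=vcov,
        converged=bool(res.success or grad_norm < 1e-5 * max(1.0, abs(ll))),
        names=list(names) + [f"mu_{j}" for j in range(1, k)],
        n=len(y),
        grad_norm=grad_norm,
    )


def fit_probit(t, Z, names=None, maxiter: int = 500) -> ProbitFit:
    """Binary probit for the treatment equation, intercept included.

    Perfect separation is reported through ``converged=False`` rather than
    silently returning a diverged fit.
    """
    t = np.asarray(t, dtype=int)
    Z = np.asarray(Z, dtype=float)
    if names is None:
        names = [f"z{i}" for i in range(Z.shape[1])]
    Zc = sm.add_constant(Z, has_constant="add")
    _check_rank(Zc, ["const"] + list(names))
    separated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            model = sm.Probit(t, Zc)
            sm_res = model.fit(disp=0, maxiter=maxiter)
        except Exception as exc:  # PerfectSeparationError in older statsmodels
            if "separation" in str(exc).lower():
                raise RuntimeError("perfect separation: probit did not converge") from exc
            raise
        separated = any("separation" in str(w.message).lower() for w in caught)
    converged = bool(sm_res.mle_retvals.get("converged", False)) and not separated
    return ProbitFit(
        gamma=np.asarray(sm_res.params),
        loglik=float(sm_res.llf),
        vcov=np.asarray(sm_res.cov_params()),
        converged=converged,
        names=["const"] + list(names),
        n=len(t),
    )


def predict_category_probs(fit: OrderedProbitFit, X) -> np.ndarray:
    """n x K matrix of category probabilities; rows sum to 1."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(fit.beta):
        raise ValueError(
            f"X has {X.shape[1]} columns but the fit expects {len(fit.beta)}"
        )
    index = X @ fit.beta
    ext = np.concatenate(([-np.inf], fit.mu, [np.inf]))
    cum = ndtr(ext[None, :] - index[:, None])
    return np.diff(cum, axis=1)
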