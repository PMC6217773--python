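"""Standard bivariate normal CDF and density, vectorized.

The joint treatment/outcome likelihood evaluates Phi2 at four points per
observation per optimizer step, so this needs to be fast and fully
vectorized.  We use Owen's identity

    Phi2(h, k; rho) = (Phi(h) + Phi(k))/2 - T(h, a_h) - T(k, a_k) - beta,

with a_h = (k - rho*h)/(h*sqrt(1-rho^2)), a_k symmetric, and beta = 1/2
when h*k < 0 (or h*k = 0 with h + k < 0), else 0.  scipy.special.owens_t
supplies T.  Exact zeros in h or k are nudged by one denormal to stay on
the continuous branch of the identity (the CDF is continuous; the error
is below double precision).
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

_RHO_CAP = 1.0 - 1e-12
_TINY = 1e-12


def bvn_cdf(h, k, rho):
    """P(U <= h, V <= k) for standard bivariate normal (U, V) with corr rho.

    Broadcasts over ``h`` and ``k``; ``rho`` is a scalar in (-1, 1).
    Infinite bounds are handled (``+inf`` marginalizes, ``-inf`` gives 0).
    """
    rho = float(np.clip(rho, -_RHO_CAP, _RHO_CAP))
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    if rho == 0.0:
        # exact independence factorization (ndtr handles infinite bounds)
        return ndtr(h) * ndtr(k)

    out = np.empty(h.shape, dtype=float)
    finite = np.isfinite(h) & np.isfinite(k)

    # infinite bounds: reduce to univariate margins
    out[~finite] = 0.0
    hi_h = np.isposinf(h) & np.isfinite(k)
    hi_k = np.isposinf(k) & np.isfinite(h)
    out[hi_h] = ndtr(k[hi_h])
    out[hi_k] = ndtr(h[hi_k])
    out[np.isposinf(h) & np.isposinf(k)] = 1.0

    hf = h[finite]
    kf = k[finite]
    # the CDF is continuous, so tiny magnitudes (where the Owen identity's
    # branch terms degenerate or underflow) can sit on the h -> 0+ branch;
    # the induced error is below phi(0) * 1e-12
    hf = np.where(np.abs(hf) < _TINY, _TINY, hf)
    kf = np.where(np.abs(kf) < _TINY, _TINY, kf)

    s = np.sqrt(1.0 - rho * rho)
    a_h = (kf - rho * hf) / (hf * s)
    a_k = (hf - rho * kf) / (kf * s)
    beta = np.where(np.signbit(hf) ^ np.signbit(kf), 0.5, 0.0)

    val = (
        0.5 * (ndtr(hf) + ndtr(kf))
        - owens_t(hf, a_h)
        - owens_t(kf, a_k)
        - beta
    )
    out[finite] = val
    np.clip(out, 0.0, 1.0, out=out)
    return out


def bvn_pdf(h, k, rho):
    """Standard bivariate normal density at (h, k); zero at infinite args."""
    rho = float(np.clip(rho, -_RHO_CAP, _RHO_CAP))
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    out = np.zeros(h.shape, dtype=float)
    finite = np.isfinite(h) & np.isfinite(k)
    hf, kf = h[finite], k[finite]
    om = 1.0 - rho * rho
    q = (hf * hf - 2.0 * rho * hf * kf + kf * kf) / om
    out[finite] = np.exp(-0.5 * q) / (2.0 * np.pi * np.sqrt(om))
    return out
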