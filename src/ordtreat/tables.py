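"""Coefficient tables and machine-readable result bundles."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .effects import MTEResult
from .etop import ETOPFit, LRTestResult
from .ordinal import OrderedProbitFit, ProbitFit

BMI_CATEGORY_NAMES = ["underweight", "normal_weight", "overweight", "obese"]


def stars(p: float) -> str:
    """Significance stars at the 0.10 / 0.05 / 0.01 levels."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def coef_table(names, est, se) -> pd.DataFrame:
    est = np.asarray(est, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    p = 2 * norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "term": list(names),
            "estimate": est,
            "se": se,
            "z": z,
            "p": p,
            "sig": [stars(v) if np.isfinite(v) else "" for v in p],
        }
    )


def oprobit_table(fit: OrderedProbitFit) -> pd.DataFrame:
    est = np.concatenate([fit.beta, fit.mu])
    return coef_table(fit.names, est, fit.se)


def probit_table(fit: ProbitFit) -> pd.DataFrame:
    return coef_table(fit.names, fit.gamma, fit.se)


def etop_tables(fit: ETOPFit) -> dict[str, pd.DataFrame]:
    """Treatment-equation and outcome-equation tables of the joint fit."""
    p = fit.params
    est = np.concatenate([p.gamma, p.beta, [p.delta], p.mu, [p.rho]])
    full = coef_table(fit.names, est, fit.se)
    n_z = len(p.gamma)
    return {
        "treatment": full.iloc[:n_z].reset_index(drop=True),
        "outcome": full.iloc[n_z:].reset_index(drop=True),
    }


def mte_table(res: MTEResult) -> pd.DataFrame:
    df = pd.DataFrame(
        {"bmi_category": BMI_CATEGORY_NAMES[: len(res.effects)], "effect": res.effects}
    )
    if res.ci_low is not None:
        df["ci_low"] = res.ci_low
        df["ci_high"] = res.ci_high
    return df


def results_bundle(
    etop_fit: ETOPFit | None = None,
    oprobit_fit: OrderedProbitFit | None = None,
    lr: LRTestResult | None = None,
    mte: MTEResult | None = None,
    meta: dict | None = None,
) -> dict:
    """JSON-serializable summary of a full run."""
    out: dict = dict(meta or {})
    if etop_fit is not None:
        p = etop_fit.params
        out["etop"] = {
            "gamma": p.gamma.tolist(),
            "beta": p.beta.tolist(),
            "delta": p.delta,
            "mu": p.mu.tolist(),
            "rho": p.rho,
            "loglik": etop_fit.loglik,
            "method": etop_fit.method,
            "converged": etop_fit.converged,
            "n": etop_fit.n,
            "names": etop_fit.names,
        }
    if oprobit_fit is not None:
        out["ordered_probit"] = {
            "beta": oprobit_fit.beta.tolist(),
            "mu": oprobit_fit.mu.tolist(),
            "loglik": oprobit_fit.loglik,
            "converged": oprobit_fit.converged,
            "names": oprobit_fit.names,
        }
    if lr is not None:
        out["lr_test"] = {
            "statistic": lr.statistic,
            "df": lr.df,
            "p_value": lr.p_value,
        }
    if mte is not None:
        out["mte"] = {
            "effects": dict(
                zip(BMI_CATEGORY_NAMES[: len(mte.effects)], mte.effects.tolist())
            ),
            "n_boot": mte.n_boot,
        }
        if mte.ci_low is not None:
            out["mte"]["ci_low"] = mte.ci_low.tolist()
            out["mte"]["ci_high"] = mte.ci_high.tolist()
    return out
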