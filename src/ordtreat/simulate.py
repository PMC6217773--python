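"""Synthetic survey generator emulating the structure of a German
general-social-survey sample (n = 3471): marginal covariate frequencies,
a gender-split continuous instrument (state smoking prevalence), and a
treatment/outcome process with known coefficients and correlated errors.

Covariates are drawn independently at their marginal frequencies (the
real joint distribution is not published); the treatment-equation
intercept is calibrated numerically so the simulated smoking share hits
its target (28.8% by default), since no constant is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import ndtr
from scipy.stats import truncnorm

from .recode import FOOD_VARS, INSTRUMENT, Dataset

DEFAULT_SEED = 20140101

#: marginal P(dummy = 1); multi-level groups handled jointly below
_MARGINS = {
    "gender_female": 1709 / 3471,
    "age": {"age_30_60": 1899 / 3468, "age_over60": 986 / 3468},
    "marital": {"married": 1998 / 3467, "divorced_widowed": 496 / 3467},
    "residence": {"bigcity": 1104 / 3470, "rural": 1360 / 3470},
    "education": {"edu_postsec": 767 / 3466, "edu_postgrad": 706 / 3466},
    "freq_wholegrain": 0.604,
    "freq_white": 0.283,
    "freq_fruit": 0.664,
    "freq_veg": 0.442,
    "freq_meat": 0.831,
    "freq_fried": 0.079,
    "freq_confect": 0.564,
}

#: treatment equation (probit index), full-sample estimates; no intercept —
#: it is calibrated to the smoking share
_GAMMA = {
    "gender_female": 0.288,
    "age_30_60": 0.283,
    "age_over60": -0.849,
    "married": -0.283,
    "divorced_widowed": 0.137,
    "bigcity": 0.026,
    "rural": -0.182,
    "edu_postsec": -0.497,
    "edu_postgrad": -0.782,
    "freq_wholegrain": -0.170,
    "freq_white": 0.189,
    "freq_fruit": -0.468,
    "freq_veg": -0.124,
    "freq_meat": 0.299,
    "freq_fried": 0.119,
    "freq_confect": -0.180,
    INSTRUMENT: 0.061,
}

#: outcome equation (latent BMI index), full-sample estimates
_BETA = {
    "gender_female": 0.329,
    "age_30_60": 0.536,
    "age_over60": 1.022,
    "married": 0.332,
    "divorced_widowed": 0.261,
    "bigcity": -0.198,
    "rural": 0.124,
    "freq_wholegrain": 0.014,
    "freq_white": -0.158,
    "freq_fruit": 0.107,
    "freq_veg": 0.014,
    "freq_meat": 0.318,
    "freq_fried": -0.067,
    "freq_confect": -0.160,
}


@dataclass
class TrueParams:
    """Ground truth for the generator; defaults are the study conditions."""

    gamma: dict = field(default_factory=lambda: dict(_GAMMA))
    beta: dict = field(default_factory=lambda: dict(_BETA))
    delta: float = 1.155
    mu: tuple = (-1.805, 1.033, 2.495)
    rho: float = -0.5
    margins: dict = field(default_factory=lambda: dict(_MARGINS))
    #: instrument mean/sd by gender (percentage points), truncated at 0
    instrument_moments: dict = field(
        default_factory=lambda: {
            "male": (30.005, 2.492),
            "female": (20.581, 2.046),
        }
    )
    smoker_share: float = 998 / 3471  # calibration target for the intercept
    gamma0: float | None = None  # filled in by calibration
    #: target P(underweight or normal weight); anchors the cutpoint location
    #: against the covariate-driven latent index (the published cutpoints
    #: presume the survey's own index distribution)
    bmi_low_share: float | None = (67 + 1503) / 3419
    mu_offset: float | None = None  # filled in by calibration

    def outcome_vars(self) -> list[str]:
        return list(self.beta)

    def treatment_vars(self) -> list[str]:
        return list(self.gamma)

    def to_dict(self) -> dict:
        return {
            "gamma": dict(self.gamma),
            "gamma0": None if self.gamma0 is None else float(self.gamma0),
            "beta": dict(self.beta),
            "delta": float(self.delta),
            "mu": [float(m) for m in self.mu],
            "mu_offset": None if self.mu_offset is None else float(self.mu_offset),
            "rho": float(self.rho),
            "smoker_share": float(self.smoker_share),
        }

    def effective_mu(self) -> np.ndarray:
        """Cutpoints after location calibration (the ground truth a fit
        on generated data should recover)."""
        off = 0.0 if self.mu_offset is None else self.mu_offset
        return np.asarray(self.mu, dtype=float) + off


def generate_covariates(
    n: int, true_params: TrueParams | None = None, seed: int = DEFAULT_SEED
) -> pd.DataFrame:
    """Draw covariates and the instrument; deterministic for a given seed."""
    if n < 1:
        raise ValueError("n must be at least 1")
    tp = true_params or TrueParams()
    rng = np.random.default_rng(seed)
    cols = {}
    for key, margin in tp.margins.items():
        if isinstance(margin, dict):
            names = list(margin)
            probs = np.array(list(margin.values()))
            if probs.sum() > 1 or (probs < 0).any():
                raise ValueError(f"invalid margins for {key}: {margin}")
            draw = rng.choice(len(names) + 1, size=n, p=[1 - probs.sum(), *probs])
            for i, name in enumerate(names, start=1):
                cols[name] = (draw == i).astype(int)
        else:
            if not 0 <= margin <= 1:
                raise ValueError(f"invalid margin for {key}: {margin}")
            cols[key] = (rng.random(n) < margin).astype(int)
    df = pd.DataFrame(cols)

    inst = np.empty(n)
    female = df["gender_female"].to_numpy().astype(bool)
    for sel, label in ((~female, "male"), (female, "female")):
        m, s = tp.instrument_moments[label]
        a = (0.0 - m) / s  # truncate at zero
        inst[sel] = truncnorm.rvs(
            a, np.inf, loc=m, scale=s, size=int(sel.sum()), random_state=rng
        )
    df[INSTRUMENT] = inst
    return df


def _design_arrays(cov: pd.DataFrame, tp: TrueParams):
    Zg = cov[list(tp.gamma)].to_numpy(dtype=float) @ np.array(list(tp.gamma.values()))
    Xb = cov[list(tp.beta)].to_numpy(dtype=float) @ np.array(list(tp.beta.values()))
    return Zg, Xb


def calibrate_intercept(tp: TrueParams, cov: pd.DataFrame) -> float:
    """Solve for gamma0 so mean Phi(gamma0 + z'gamma) hits the target share."""
    Zg, _ = _design_arrays(cov, tp)
    f = lambda g0: float(np.mean(ndtr(g0 + Zg))) - tp.smoker_share
    return brentq(f, -30.0, 30.0, xtol=1e-10)


def calibrate_mu_offset(tp: TrueParams, cov: pd.DataFrame, gamma0: float) -> float:
    """Shift for the cutpoints so the model-implied P(Y <= 2) matches the
    target low-BMI share, accounting for the endogenous treatment.

    P(Y* <= m | x, z) = Phi2(m - xb, -c; rho)
                      + Phi(m - xb - delta) - Phi2(m - xb - delta, -c; rho).
    """
    from ._bvn import bvn_cdf

    Zg, Xb = _design_arrays(cov, tp)
    c = gamma0 + Zg
    mu2 = float(tp.mu[1])

    def implied_low_share(off):
        m = mu2 + off
        a0 = m - Xb
        a1 = m - Xb - tp.delta
        p = bvn_cdf(a0, -c, tp.rho) + ndtr(a1) - bvn_cdf(a1, -c, tp.rho)
        return float(np.mean(p)) - tp.bmi_low_share

    return brentq(implied_low_share, -30.0, 30.0, xtol=1e-10)


def simulate_treatment_outcome(
    covariates: pd.DataFrame,
    true_params: TrueParams | None = None,
    seed: int = DEFAULT_SEED,
) -> Dataset:
    """Draw (T, Y) given covariates under the bivariate-normal error model."""
    tp = true_params or TrueParams()
    missing = [v for v in list(tp.gamma) + list(tp.beta) if v not in covariates]
    if missing:
        raise ValueError(f"covariates lack generator variables: {sorted(set(missing))}")
    rng = np.random.default_rng(seed)
    n = len(covariates)
    gamma0 = tp.gamma0 if tp.gamma0 is not None else calibrate_intercept(tp, covariates)
    Zg, Xb = _design_arrays(covariates, tp)

    cov_ve = np.array([[1.0, tp.rho], [tp.rho, 1.0]])
    L = np.linalg.cholesky(cov_ve)
    errs = rng.standard_normal((n, 2)) @ L.T
    v, eps = errs[:, 0], errs[:, 1]

    t = (gamma0 + Zg + v > 0).astype(int)
    ystar = Xb + tp.delta * t + eps
    mu = np.asarray(tp.mu, dtype=float)
    if tp.mu_offset is not None:
        mu = mu + tp.mu_offset
    elif tp.bmi_low_share is not None:
        mu = mu + calibrate_mu_offset(tp, covariates, gamma0)
    y = 1 + np.searchsorted(mu, ystar, side="left")

    cov_cols = [c for c in covariates.columns if c != INSTRUMENT]
    return Dataset(
        y=y,
        t=t,
        covariates=covariates[cov_cols].astype(int).reset_index(drop=True),
        instrument=covariates[INSTRUMENT].to_numpy(),
    )


def simulate_dataset(
    n: int,
    true_params: TrueParams | None = None,
    seed: int = DEFAULT_SEED,
) -> tuple[Dataset, TrueParams]:
    """Covariates + treatment/outcome in one call; returns the params with
    the calibrated intercept filled in."""
    tp = true_params or TrueParams()
    cov = generate_covariates(n, tp, seed=seed)
    if tp.gamma0 is None:
        tp = replace(tp, gamma0=calibrate_intercept(tp, cov))
    if tp.mu_offset is None and tp.bmi_low_share is not None:
        tp = replace(tp, mu_offset=calibrate_mu_offset(tp, cov, tp.gamma0))
    ds = simulate_treatment_outcome(cov, tp, seed=seed + 1)
    return ds, tp


def scenario_params(name: str) -> TrueParams:
    """Named ground-truth scenarios.

    'paper'    — default coefficients, rho = -0.5
    'null'     — rho = 0 (no endogeneity)
    'strongrho'— rho = -0.8
    'weakiv'   — instrument coefficient 0 (weak identification)
    """
    tp = TrueParams()
    if name == "paper":
        return tp
    if name == "null":
        return replace(tp, rho=0.0)
    if name == "strongrho":
        return replace(tp, rho=-0.8)
    if name == "weakiv":
        gamma = dict(tp.gamma)
        # all exclusion restrictions uninformative, not just the instrument
        gamma[INSTRUMENT] = 0.0
        gamma["edu_postsec"] = 0.0
        gamma["edu_postgrad"] = 0.0
        return replace(tp, gamma=gamma)
    raise ValueError(f"unknown scenario {name!r}")


def compact_params(rho: float = 0.0, delta: float = 1.0) -> TrueParams:
    """A small design for repeated-fit studies (test-size calibration,
    power curves) where fit speed matters more than covariate realism.

    Keeps the study's identification structure — the continuous instrument
    plus the two education dummies as exclusion restrictions — but only
    two outcome-equation covariates."""
    return TrueParams(
        gamma={
            "gender_female": 0.3,
            "age_over60": -0.8,
            "edu_postsec": -0.497,
            "edu_postgrad": -0.782,
            INSTRUMENT: 0.061,
        },
        beta={"gender_female": 0.33, "age_over60": 1.0},
        delta=delta,
        rho=rho,
        margins={
            "gender_female": _MARGINS["gender_female"],
            "age_over60": 986 / 3468,
            "education": dict(_MARGINS["education"]),
        },
    )


def compact_model_spec():
    """ModelSpec matching :func:`compact_params`."""
    from .recode import ModelSpec

    return ModelSpec(
        outcome_vars=["gender_female", "age_over60"],
        treatment_vars=[
            "gender_female",
            "age_over60",
            "edu_postsec",
            "edu_postgrad",
            INSTRUMENT,
        ],
    )


def make_replication_suite(n: int, seed: int = DEFAULT_SEED, outdir=None) -> dict:
    """Generate the four named scenarios; optionally write CSV + YAML
    manifests to ``outdir``.  Returns {scenario: (Dataset, TrueParams)}."""
    from pathlib import Path

    bundle = {}
    for i, name in enumerate(["paper", "null", "strongrho", "weakiv"]):
        tp = scenario_params(name)
        ds, tp = simulate_dataset(n, tp, seed=seed + 1000 * i)
        bundle[name] = (ds, tp)
        if outdir is not None:
            out = Path(outdir)
            out.mkdir(parents=True, exist_ok=True)
            ds.to_frame().to_csv(out / f"{name}.csv", index=False)
            manifest = tp.to_dict() | {"n": n, "seed": seed + 1000 * i}
            with open(out / f"{name}.yaml", "w") as fh:
                yaml.safe_dump(manifest, fh, sort_keys=False)
    return bundle


# canonical raw-CSV levels used when exporting a recoded Dataset back to
# the survey schema (round-trip testing and example inputs)
_RAW_LEVELS = {
    "age_band": [("age_30_60", "30-60"), ("age_over60", ">60")],
    "marital": [("married", "married"), ("divorced_widowed", "divorced/widowed")],
    "residence": [("bigcity", "big city"), ("rural", "village/rural")],
    "education": [("edu_postsec", "post-secondary"), ("edu_postgrad", "postgraduate")],
}
_RAW_REFERENCE = {
    "age_band": "18-29",
    "marital": "single",
    "residence": "town",
    "education": "up to secondary",
}


def dataset_to_raw(ds: Dataset) -> pd.DataFrame:
    """Express a recoded Dataset in the raw survey-CSV schema.

    Frequency flags map to canonical scale levels (1 = several times a
    day for frequent, 7 = never otherwise), BMI class is written as
    ``bmi_cat``, and dummies are folded back into labeled categoricals.
    Reading the result back reproduces the Dataset exactly.
    """
    cov = ds.covariates
    out = pd.DataFrame()
    out["bmi_cat"] = ds.y
    out["smoker"] = ds.t
    for food in FOOD_VARS:
        raw = "ff_" + food.removeprefix("freq_")
        out[raw] = np.where(cov[food] == 1, 1, 7)
    out["gender"] = np.where(cov["gender_female"] == 1, "female", "male")
    for col, pairs in _RAW_LEVELS.items():
        lab = pd.Series(_RAW_REFERENCE[col], index=cov.index)
        for dummy, level in pairs:
            if dummy in cov:
                lab[cov[dummy] == 1] = level
        out[col] = lab.to_numpy()
    out[INSTRUMENT] = ds.instrument
    return out
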