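"""Survey recoding: BMI categories, food-frequency dichotomization, dummy
coding, and design-matrix construction.

The analysis dataset has a four-level ordinal body-weight outcome (WHO BMI
classes), a binary smoking indicator, dummy-coded sociodemographics, seven
frequent-consumption flags, and a continuous instrument (state-level
smoking prevalence, in percentage points).  Education and the instrument
enter only the treatment (smoking) equation — the exclusion restrictions
that identify the treatment effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

# WHO BMI cut-offs; upper class is left-closed (BMI = 25.0 is overweight).
BMI_CUTOFFS = (18.5, 25.0, 30.0)
BMI_LABELS = ("underweight", "normal", "overweight", "obese")

# 7-point frequency scale, 1 = several times a day ... 7 = never.
# "Frequent" means at least daily for breads/fruit/vegetables (level <= 2)
# and at least several times a week for meat/fried/confectionery (<= 3).
DAILY_CUTOFF_GROUPS = ("wholegrain", "white", "fruit", "veg")
WEEKLY_CUTOFF_GROUPS = ("meat", "fried", "confect")
FOOD_GROUPS = DAILY_CUTOFF_GROUPS + WEEKLY_CUTOFF_GROUPS

SOCIO_VARS = [
    "gender_female",
    "age_30_60",
    "age_over60",
    "married",
    "divorced_widowed",
    "bigcity",
    "rural",
]
FOOD_VARS = [f"freq_{g}" for g in FOOD_GROUPS]
EDU_VARS = ["edu_postsec", "edu_postgrad"]
INSTRUMENT = "smoke_prev"

#: categorical level -> dummy column; omitted levels are the reference
#: categories (age 18-29, single, town, up to secondary education).
CATEGORY_DUMMIES = {
    "gender": {"male": {}, "female": {"gender_female": 1}},
    "age_band": {
        "18-29": {},
        "30-60": {"age_30_60": 1},
        ">60": {"age_over60": 1},
    },
    "marital": {
        "single": {},
        "married": {"married": 1},
        "divorced/widowed": {"divorced_widowed": 1},
    },
    "residence": {
        "town": {},
        "big city": {"bigcity": 1},
        "village/rural": {"rural": 1},
    },
    "education": {
        "up to secondary": {},
        "post-secondary": {"edu_postsec": 1},
        "postgraduate": {"edu_postgrad": 1},
    },
}

RAW_FOOD_COLUMNS = {
    "ff_wholegrain": "wholegrain",
    "ff_white": "white",
    "ff_fruit": "fruit",
    "ff_veg": "veg",
    "ff_meat": "meat",
    "ff_fried": "fried",
    "ff_confect": "confect",
}

MANDATORY_COLUMNS = (
    ["smoker", "gender", "age_band", "marital", "residence", "education"]
    + list(RAW_FOOD_COLUMNS)
    + ["smoke_prev"]
)


def bmi_category(weight: float, height: float) -> int:
    """WHO BMI class (1 underweight ... 4 obese) from weight [kg], height [m]."""
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise ValueError("weight and height must be positive")
    bmi = weight / height**2
    cat = 1 + np.searchsorted(BMI_CUTOFFS, bmi, side="right")
    return int(cat) if np.isscalar(cat) or cat.ndim == 0 else cat


def dichotomize_frequency(level, group: str):
    """Collapse a 7-point intake frequency to a frequent-consumption flag.

    Breads, fruit and vegetables are "frequent" at least daily (level <= 2);
    meat products, fried foods and confectionery at least several times a
    week (level <= 3).
    """
    if group not in FOOD_GROUPS:
        raise ValueError(f"unknown food group {group!r}; expected one of {FOOD_GROUPS}")
    level = np.asarray(level)
    if np.any((level < 1) | (level > 7)):
        raise ValueError("frequency level must be in 1..7")
    cut = 2 if group in DAILY_CUTOFF_GROUPS else 3
    flag = (level <= cut).astype(int)
    return int(flag) if flag.ndim == 0 else flag


@dataclass
class ModelSpec:
    """Variable lists for the outcome (X) and treatment (Z) equations.

    ``treatment_vars`` must strictly contain ``outcome_vars``; the extras
    (education dummies and the instrument, by default) are the exclusion
    restrictions.
    """

    outcome_vars: list[str] = field(
        default_factory=lambda: SOCIO_VARS + FOOD_VARS
    )
    treatment_vars: list[str] = field(
        default_factory=lambda: SOCIO_VARS + FOOD_VARS + EDU_VARS + [INSTRUMENT]
    )
    reference_categories: dict[str, str] = field(
        default_factory=lambda: {
            "gender": "male",
            "age_band": "18-29",
            "marital": "single",
            "residence": "town",
            "education": "up to secondary",
        }
    )

    def __post_init__(self):
        missing = set(self.outcome_vars) - set(self.treatment_vars)
        if missing:
            raise ValueError(
                f"treatment_vars must contain all outcome_vars; missing {sorted(missing)}"
            )
        if not self.extras:
            raise ValueError(
                "no exclusion restriction: treatment_vars must strictly "
                "extend outcome_vars by at least one instrument"
            )

    @property
    def extras(self) -> list[str]:
        return [v for v in self.treatment_vars if v not in self.outcome_vars]

    def drop_var(self, name: str) -> "ModelSpec":
        """Copy of the spec without ``name`` (e.g. the gender dummy in
        gender-stratified fits)."""
        return ModelSpec(
            outcome_vars=[v for v in self.outcome_vars if v != name],
            treatment_vars=[v for v in self.treatment_vars if v != name],
            reference_categories=dict(self.reference_categories),
        )


@dataclass
class Dataset:
    """Analysis-ready respondent data (complete cases only)."""

    y: np.ndarray  # ordinal outcome 1..4
    t: np.ndarray  # smoking indicator 0/1
    covariates: pd.DataFrame  # binary indicator columns
    instrument: np.ndarray  # smoking prevalence, percentage points

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        self.t = np.asarray(self.t, dtype=int)
        self.instrument = np.asarray(self.instrument, dtype=float)
        n = len(self.y)
        if not (len(self.t) == len(self.covariates) == len(self.instrument) == n):
            raise ValueError("all Dataset components must have equal length")
        if not np.isin(self.y, [1, 2, 3, 4]).all():
            raise ValueError("y must take values in {1, 2, 3, 4}")
        if not np.isin(self.t, [0, 1]).all():
            raise ValueError("t must be binary")
        vals = self.covariates.to_numpy()
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("covariates must be binary indicators")

    def __len__(self) -> int:
        return len(self.y)

    def to_frame(self) -> pd.DataFrame:
        df = self.covariates.copy()
        df.insert(0, "t", self.t)
        df.insert(0, "y", self.y)
        df[INSTRUMENT] = self.instrument
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Dataset":
        cov = df.drop(columns=["y", "t", INSTRUMENT])
        return cls(
            y=df["y"].to_numpy(),
            t=df["t"].to_numpy(),
            covariates=cov.reset_index(drop=True).astype(int),
            instrument=df[INSTRUMENT].to_numpy(),
        )

    def subset(self, mask: np.ndarray) -> "Dataset":
        mask = np.asarray(mask, dtype=bool)
        return Dataset(
            y=self.y[mask],
            t=self.t[mask],
            covariates=self.covariates.loc[mask].reset_index(drop=True),
            instrument=self.instrument[mask],
        )

    def stratum(self, column: str, value: int) -> "Dataset":
        """Rows with ``covariates[column] == value``, with the column dropped.

        Used for gender-stratified fits (filter, do not interact)."""
        mask = self.covariates[column].to_numpy() == value
        sub = self.subset(mask)
        sub.covariates = sub.covariates.drop(columns=[column])
        return sub


@dataclass
class DesignData:
    """Row-aligned numeric design matrices for the two equations."""

    y: np.ndarray
    t: np.ndarray
    X: pd.DataFrame  # outcome equation (no education, no instrument)
    Z: pd.DataFrame  # treatment equation (adds the exclusion restrictions)

    @property
    def n(self) -> int:
        return len(self.y)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def _remap(df: pd.DataFrame, config: dict | None) -> pd.DataFrame:
    if not config:
        return df
    cols = config.get("columns")
    if cols:
        df = df.rename(columns={v: k for k, v in cols.items()})
    levels = config.get("levels")
    if levels:
        for col, mapping in levels.items():
            if col in df.columns:
                df[col] = df[col].replace(mapping)
    if config.get("scale_direction") == "7_most_frequent":
        # raw scale runs the other way; flip to 1 = most frequent
        for col in RAW_FOOD_COLUMNS:
            if col in df.columns:
                df[col] = 8 - df[col]
    return df


def recode_frame(df: pd.DataFrame, spec: ModelSpec | None = None) -> Dataset:
    """Apply all variable constructions to a raw respondent table."""
    spec = spec or ModelSpec()
    df = df.copy()

    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise KeyError(f"missing mandatory column {col!r}")
    if "bmi_cat" not in df.columns and not {"weight_kg", "height_m"} <= set(df.columns):
        raise KeyError("need either 'bmi_cat' or both 'weight_kg' and 'height_m'")

    if "bmi_cat" not in df.columns:
        df["bmi_cat"] = np.nan
    needs_bmi = df["bmi_cat"].isna()
    if needs_bmi.any() and {"weight_kg", "height_m"} <= set(df.columns):
        w = df.loc[needs_bmi, "weight_kg"]
        h = df.loc[needs_bmi, "height_m"]
        ok = w.notna() & h.notna() & (w > 0) & (h > 0)
        idx = w.index[ok]
        df.loc[idx, "bmi_cat"] = 1 + np.searchsorted(
            BMI_CUTOFFS, (w[ok] / h[ok] ** 2).to_numpy(), side="right"
        )

    out = pd.DataFrame(index=df.index)
    out["y"] = df["bmi_cat"]
    out["t"] = df["smoker"]

    for raw_col, group in RAW_FOOD_COLUMNS.items():
        lv = df[raw_col]
        cut = 2 if group in DAILY_CUTOFF_GROUPS else 3
        flag = (lv <= cut).astype(float)
        flag[lv.isna() | (lv < 1) | (lv > 7)] = np.nan
        out[f"freq_{group}"] = flag

    for cat_col, level_map in CATEGORY_DUMMIES.items():
        dummy_names = sorted({d for dums in level_map.values() for d in dums})
        known = df[cat_col].isin(level_map)
        for name in dummy_names:
            col = pd.Series(0.0, index=df.index)
            for level, dums in level_map.items():
                if name in dums:
                    col[df[cat_col] == level] = 1.0
            col[~known] = np.nan
            out[name] = col

    out[INSTRUMENT] = df[INSTRUMENT]

    needed = ["y", "t"] + list(dict.fromkeys(spec.treatment_vars)) + [
        v for v in spec.outcome_vars if v not in spec.treatment_vars
    ]
    needed = [c for c in needed if c in out.columns]
    complete = out[needed].notna().all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("listwise deletion dropped %d of %d rows", dropped, len(out))
    out = out.loc[complete].reset_index(drop=True)

    cov_cols = [c for c in out.columns if c not in ("y", "t", INSTRUMENT)]
    return Dataset(
        y=out["y"].to_numpy(),
        t=out["t"].to_numpy(),
        covariates=out[cov_cols].astype(int),
        instrument=out[INSTRUMENT].to_numpy(),
    )


def read_survey_csv(path, spec: ModelSpec | None = None, config=None) -> Dataset:
    """Read a raw respondent CSV and return the recoded complete-case Dataset.

    ``config`` may be a dict or a YAML path providing column/level remapping
    and the food-frequency scale direction flag.
    """
    if isinstance(config, (str,)) or hasattr(config, "__fspath__"):
        config = load_config(config)
    df = pd.read_csv(path)
    df = _remap(df, config)
    return recode_frame(df, spec)


def build_design(dataset: Dataset, spec: ModelSpec | None = None) -> DesignData:
    """Assemble (y, t, X, Z) with the exclusion restrictions applied.

    X holds the outcome-equation regressors; Z adds the education dummies
    and the instrument.  Warns if the instrument is constant in-sample
    (weak identification).
    """
    spec = spec or ModelSpec()
    frame = dataset.covariates.copy()
    frame[INSTRUMENT] = dataset.instrument
    missing = [v for v in spec.treatment_vars if v not in frame.columns]
    if missing:
        raise KeyError(f"spec variables not in dataset: {missing}")

    X = frame[list(spec.outcome_vars)].astype(float)
    Z = frame[list(spec.treatment_vars)].astype(float)
    extras = Z[spec.extras]
    if (extras.nunique() <= 1).all():
        import warnings

        warnings.warn(
            "all exclusion-restriction variables are constant in-sample: "
            "identification is weak",
            UserWarning,
            stacklevel=2,
        )
    return DesignData(y=dataset.y.copy(), t=dataset.t.copy(), X=X, Z=Z)
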