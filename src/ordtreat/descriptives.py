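"""Sample descriptives: cross-tabulations, Pearson chi-square tests and
two-sample t-tests, laid out like a survey characteristics table with
counts and percentages overall and by gender.

Conventions: no Yates continuity correction; percentage denominators are
per-variable valid Ns; p-values display to three decimals with values
below 0.0005 shown as "0.000".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .recode import INSTRUMENT, Dataset


@dataclass
class ContingencyTable:
    counts: pd.DataFrame  # rows x columns of non-negative ints

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def with_margins(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["Total"] = self.row_totals
        out.loc["Total"] = out.sum(axis=0)
        return out


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float

    def format_p(self) -> str:
        return f"{self.p_value:.3f}"


def crosstab(a, b) -> ContingencyTable:
    """Cross-tabulate two categorical vectors, pairwise-dropping missing."""
    a = pd.Series(a)
    b = pd.Series(np.asarray(b), index=a.index)
    ok = a.notna() & b.notna()
    if not ok.any():
        raise ValueError("no complete pairs to tabulate")
    return ContingencyTable(pd.crosstab(a[ok], b[ok]))


def pearson_chi2(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence (no continuity correction)."""
    counts = table.counts.to_numpy()
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column total")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return TestResult(statistic=float(stat), df=int(df), p_value=float(p))


def two_sample_t(values, groups, pooled: bool = False) -> TestResult:
    """Two-sided two-sample t-test of the group means.

    ``pooled=True`` gives the equal-variance (Student) form, otherwise
    Welch.  Missing values are dropped pairwise.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError("groups must contain exactly two levels")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    res = stats.ttest_ind(a, b, equal_var=pooled)
    if pooled:
        df = len(a) + len(b) - 2
    else:
        df = int(np.floor(res.df))
    return TestResult(statistic=float(res.statistic), df=df, p_value=float(res.pvalue))


def _cat_block(name, codes, labels, by, rows):
    """Append count/percent rows for one categorical variable."""
    codes = pd.Series(codes)
    valid = codes.notna()
    n_valid = int(valid.sum())
    tab = crosstab(codes, by)
    test = (
        pearson_chi2(tab)
        if tab.counts.shape[0] >= 2 and tab.counts.shape[1] >= 2
        else None
    )
    rows.append(
        {
            "variable": name,
            "level": "",
            "n": n_valid,
            "percent": np.nan,
            "chi2": test.statistic if test else np.nan,
            "df": test.df if test else np.nan,
            "p_value": test.p_value if test else np.nan,
        }
    )
    by = pd.Series(np.asarray(by), index=codes.index)
    for level in labels:
        sel = codes == level
        cnt = int(sel.sum())
        row = {
            "variable": name,
            "level": str(level),
            "n": cnt,
            "percent": 100.0 * cnt / n_valid if n_valid else np.nan,
            "chi2": np.nan,
            "df": np.nan,
            "p_value": np.nan,
        }
        for g in (0, 1):
            gsel = by == g
            gn = int((codes[gsel].notna()).sum())
            gcnt = int((sel & gsel).sum())
            row[f"n_g{g}"] = gcnt
            row[f"pct_g{g}"] = 100.0 * gcnt / gn if gn else np.nan
        rows.append(row)


def summary_table(dataset: Dataset, by: str = "gender_female") -> pd.DataFrame:
    """Characteristics table: counts/percentages overall and by group,
    chi-square per categorical variable, t-test for the instrument."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    grp = dataset.covariates[by].to_numpy()
    rows: list[dict] = []

    _cat_block("bmi_category", dataset.y, [1, 2, 3, 4], grp, rows)
    _cat_block("smoker", dataset.t, [0, 1], grp, rows)
    for col in dataset.covariates.columns:
        if col == by:
            continue
        _cat_block(col, dataset.covariates[col].to_numpy(), [0, 1], grp, rows)

    if len(np.unique(grp)) == 2:
        test = two_sample_t(dataset.instrument, grp)
        t_stat, t_df, t_p = test.statistic, test.df, test.p_value
    else:
        t_stat = t_df = t_p = np.nan
    inst = {
        "variable": INSTRUMENT,
        "level": "mean (sd)",
        "n": len(dataset),
        "percent": np.nan,
        "chi2": np.nan,
        "df": t_df,
        "p_value": t_p,
        "t_stat": t_stat,
    }
    for g in (0, 1):
        vals = dataset.instrument[grp == g]
        inst[f"mean_g{g}"] = float(np.mean(vals)) if len(vals) else np.nan
        inst[f"sd_g{g}"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
    rows.append(inst)
    return pd.DataFrame(rows)


def format_p(p: float) -> str:
    """Three-decimal p-value, floored display below 0.0005."""
    return "0.000" if p < 0.0005 else f"{p:.3f}"


def report_markdown(table: pd.DataFrame) -> str:
    df = table.copy()
    if "p_value" in df:
        df["p_value"] = df["p_value"].map(
            lambda p: "" if pd.isna(p) else format_p(p)
        )
    return df.to_markdown(index=False, floatfmt=".3f")
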