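"""Cohort characteristic tables and the tests that accompany them.

Categorical characteristics (zygosity, bacterial vaginosis, smoking)
are compared across ancestry strata with the continuity-corrected
(Yates) chi-square test on 2x2 tables; continuous characteristics
(BMI, age, pH) with the unequal-variance Welch t-test computed from
group summaries, so the tests can be reproduced directly from a
published descriptive table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_cohort import ParticipantRecord

__all__ = [
    "ContingencyTable2x2",
    "GroupSummary",
    "chi2_yates",
    "welch_t",
    "summarize_cohort",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 cross-classification: rows = ancestry groups, columns = outcome."""

    cells: tuple  # ((a, b), (c, d)) nonnegative integers

    def __post_init__(self):
        arr = np.asarray(self.cells)
        if arr.shape != (2, 2):
            raise ValueError("expected a 2x2 table")
        if np.any(arr < 0):
            raise ValueError("cell counts must be nonnegative")
        if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
            raise ValueError("zero margin: test undefined")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.cells, dtype=float)


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient summary of one group's continuous measurements."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


def chi2_yates(table: ContingencyTable2x2, correction: bool = True) -> tuple:
    """Chi-square test of independence on a 2x2 table.

    With ``correction=True`` (default) the Yates continuity correction
    is applied, capped so a cell with |O - E| < 0.5 contributes zero
    rather than going negative.  Returns ``(statistic, p_value)`` with
    the p-value from the chi-square(1) upper tail.
    """
    res = stats.chi2_contingency(table.as_array(), correction=correction)
    return float(res.statistic), float(res.pvalue)


def welch_t(g1: GroupSummary, g2: GroupSummary) -> tuple:
    """Welch's unequal-variance t-test from group summaries.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of
    freedom and a two-sided p-value.  Two degenerate groups with equal
    means give (0, ., 1) by convention.
    """
    if g1.sd == 0.0 and g2.sd == 0.0:
        if g1.mean == g2.mean:
            return 0.0, float(g1.n + g2.n - 2), 1.0
        raise ZeroDivisionError("both groups have zero variance but unequal means")
    res = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=False
    )
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


_CONTINUOUS = [("bmi", "BMI"), ("age", "Age"), ("ph", "Sample pH")]
_CATEGORICAL = [
    ("zygosity", "Zygosity", ("MZ", "DZ"), ()),
    ("bacterial_vaginosis", "Bacterial vaginosis", ("no", "yes"), ("not_sure",)),
    ("current_smoking", "Current smoking", ("no", "yes"), ()),
]


def summarize_cohort(records: list, ancestries: tuple | None = None) -> pd.DataFrame:
    """Build a descriptive characteristics table by ancestry stratum.

    Continuous variables get min / median (IQR) / mean (sd) / max and a
    missing count, plus a Welch t-test across the first two strata;
    categorical variables get level counts and a Yates chi-square test.
    For bacterial vaginosis the "not sure" level is excluded from the
    test (it is neither outcome), and missing values are always
    excluded; this is required for the tests to be well-defined 2x2
    comparisons.
    """
    df = _records_frame(records)
    if ancestries is None:
        ancestries = tuple(sorted(df["ancestry"].unique()))
    rows = []
    for key, label, levels, excluded in _CATEGORICAL:
        counts = {}
        for anc in ancestries:
            sub = df.loc[df["ancestry"] == anc, key]
            counts[anc] = {lvl: int((sub == lvl).sum()) for lvl in levels}
            counts[anc]["missing"] = int(sub.isna().sum())
        stat = p = np.nan
        if len(ancestries) >= 2:
            a, b = ancestries[0], ancestries[1]
            cells = ((counts[a][levels[0]], counts[a][levels[1]]),
                     (counts[b][levels[0]], counts[b][levels[1]]))
            try:
                stat, p = chi2_yates(ContingencyTable2x2(cells))
            except ValueError:
                pass
        for anc in ancestries:
            for lvl in levels:
                rows.append((label, anc, lvl, counts[anc][lvl], stat, p))
            rows.append((label, anc, "missing", counts[anc]["missing"], stat, p))
    for key, label in _CONTINUOUS:
        summaries = {}
        for anc in ancestries:
            sub = df.loc[df["ancestry"] == anc, key].dropna().astype(float)
            if len(sub) >= 2:
                summaries[anc] = GroupSummary(
                    mean=float(sub.mean()), sd=float(sub.std(ddof=1)), n=len(sub)
                )
        stat = p = np.nan
        if len(ancestries) >= 2 and all(a in summaries for a in ancestries[:2]):
            stat, _, p = welch_t(summaries[ancestries[0]], summaries[ancestries[1]])
        for anc in ancestries:
            sub = df.loc[df["ancestry"] == anc, key].dropna().astype(float)
            if len(sub) == 0:
                continue
            q1, med, q3 = np.percentile(sub, [25, 50, 75])
            for name, val in [
                ("min", sub.min()),
                ("median", med),
                ("iqr_low", q1),
                ("iqr_high", q3),
                ("mean", sub.mean()),
                ("sd", sub.std(ddof=1) if len(sub) > 1 else 0.0),
                ("max", sub.max()),
                ("missing", float(df.loc[df["ancestry"] == anc, key].isna().sum())),
            ]:
                rows.append((label, anc, name, float(val), stat, p))
    return pd.DataFrame(
        rows, columns=["variable", "ancestry", "statistic", "value", "test_stat", "p_value"]
    )


def _records_frame(records: list) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "participant_id": r.participant_id,
            "ancestry": r.ancestry,
            "zygosity": r.zygosity,
            "age": r.age,
        }
        for key in ("bmi", "bacterial_vaginosis", "ph", "current_smoking"):
            row[key] = r.covariates.get(key)
        rows.append(row)
    return pd.DataFrame(rows)
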