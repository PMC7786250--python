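"""Agreement and descriptive statistics: ICC, Bland-Altman, group tests.

Inter-reader and test-retest reliability of an NWU measurement is summarised
by the intraclass correlation coefficient; agreement between two measurement
*methods* by Bland-Altman bias and 95% limits of agreement.  Reliability
above ICC 0.75 is conventionally read as good.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BlandAltmanResult",
    "icc_agreement",
    "bland_altman",
    "cohort_compare",
]


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    outside_count: int
    n: int
    p_bias: float


def _validate_table(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table, dtype=np.float64)
    if t.ndim != 2 or t.shape[0] < 3 or t.shape[1] < 2:
        raise ValueError("rating table needs >= 3 subjects and >= 2 raters")
    if not np.all(np.isfinite(t)):
        raise ValueError("rating table must have no missing cells")
    return t


def icc_agreement(
    table: Sequence[Sequence[float]] | np.ndarray,
    form: Literal["icc2", "icc3"] = "icc2",
) -> float:
    """Single-measurement intraclass correlation of a subjects-x-raters table.

    Default is ICC(2,1): two-way random effects, absolute agreement, single
    measurement — the standard form for interchangeable raters measuring the
    same subjects.  ICC(3,1) (consistency, fixed raters) is available.  A
    table with zero between-subject variance is degenerate and returns NaN.
    """
    import pandas as pd
    import pingouin as pg

    t = _validate_table(table)
    n, k = t.shape
    if np.isclose(t.mean(axis=1).var(), 0.0):  # no between-subject variance
        return float("nan")
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": t.ravel(),
        }
    )
    res = pg.intraclass_corr(
        data=long, targets="subject", raters="rater", ratings="score"
    ).set_index("Type")
    # label depends on the pingouin version: Shrout-Fleiss vs McGraw-Wong
    keys = ("ICC2", "ICC(A,1)") if form == "icc2" else ("ICC3", "ICC(C,1)")
    key = next(k for k in keys if k in res.index)
    value = float(res.loc[key, "ICC"])
    if np.isnan(value):
        return float("nan")
    return value


def bland_altman(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> BlandAltmanResult:
    """Bland-Altman agreement of two paired measurement series.

    Differences d = x - y; bias = mean(d); limits of agreement are
    bias +/- 1.96 * SD(d) (sample SD); ``p_bias`` is the two-sided paired
    t-test of the differences against zero.  Zero-variance differences
    collapse the limits onto the bias, with p = 1 when the bias is 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D series of length >= 3")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    outside = int(((d < lo) | (d > hi)).sum())
    if sd == 0:
        p = 1.0 if bias == 0 else 0.0
    else:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return BlandAltmanResult(
        bias=bias, loa_low=lo, loa_high=hi, sd_diff=sd,
        outside_count=outside, n=int(d.size), p_bias=p,
    )


def cohort_compare(
    group_a: Sequence,
    group_b: Sequence,
    variable_type: Literal["continuous", "categorical"] = "continuous",
) -> tuple[float, float]:
    """Two-group descriptive comparison: t-test or chi-squared.

    Continuous variables get a two-sided two-sample t-test; categorical
    variables a chi-squared test on the group-by-category contingency table.
    Returns ``(statistic, p)``.
    """
    a = np.asarray(group_a)
    b = np.asarray(group_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if variable_type == "continuous":
        a = a.astype(np.float64)
        b = b.astype(np.float64)
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if float(a.mean()) == float(b.mean()):
                raise ValueError(
                    "both groups are constant and equal; the t statistic is undefined "
                    "(0/0) — compare these as categorical data instead"
                )
            raise ValueError("zero variance in both groups; t-test is undefined")
        stat, p = stats.ttest_ind(a, b)
        return float(stat), float(p)
    if variable_type == "categorical":
        cats = np.unique(np.concatenate([a, b]))
        if cats.size < 2:
            raise ValueError("need at least two categories for a chi-squared test")
        obs = np.array(
            [[(g == c).sum() for c in cats] for g in (a, b)], dtype=np.float64
        )
        stat, p, _, _ = stats.chi2_contingency(obs)
        return float(stat), float(p)
    raise ValueError(f"unknown variable_type {variable_type!r}")
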