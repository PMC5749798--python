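"""Likert aggregation and agreement statistics for method comparison.

Covers the single-stimulus side of a rating study and the statistics used
to compare it with pairwise-comparison scores: per-stimulus mean Likert
ratings, the two-way consistency intraclass correlation (average
measures), Pearson correlations between score vectors, Williams's t for
two dependent overlapping correlations, first-r rater subsetting, and
five-number descriptive summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import TrialSequence

__all__ = [
    "MeasureSummary",
    "ICCResult",
    "WilliamsResult",
    "mean_likert",
    "icc_consistency_avg",
    "pearson",
    "williams_t",
    "rater_subset",
    "summarize",
]


@dataclass(frozen=True)
class MeasureSummary:
    mean: float
    sd: float
    median: float
    minimum: float
    maximum: float


@dataclass(frozen=True)
class ICCResult:
    """Two-way consistency ICC, average measures, with its 95% CI."""

    icc: float
    ci_lower: float
    ci_upper: float
    ms_rows: float
    ms_error: float
    df1: int
    df2: int


@dataclass(frozen=True)
class WilliamsResult:
    t: float
    df: int
    p: float


def _as_matrix(ratings: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(ratings, pd.DataFrame):
        raise TypeError("ratings must be a stimuli x raters DataFrame")
    return ratings


def mean_likert(ratings: pd.DataFrame) -> pd.Series:
    """Per-stimulus arithmetic mean over the raters that rated it.

    Missing entries are allowed; a stimulus with no ratings at all is an
    error (its mean would be undefined).
    """
    ratings = _as_matrix(ratings)
    counts = ratings.notna().sum(axis=1)
    empty = counts[counts == 0].index.tolist()
    if empty:
        raise ValueError(
            "stimuli with no ratings: " + ", ".join(map(str, empty))
        )
    return ratings.mean(axis=1).rename("mean_likert")


def icc_consistency_avg(
    ratings: pd.DataFrame, confidence: float = 0.95
) -> ICCResult:
    """Intraclass correlation: two-way model, consistency type, average
    measures (ICC(C,k) in the Shrout-Fleiss scheme, a.k.a. ICC3k).

    From the two-way ANOVA mean squares of a complete stimuli x raters
    matrix: ICC = (MS_rows - MS_error) / MS_rows, where MS_error is the
    stimulus x rater interaction mean square.  Additive per-rater offsets
    leave it unchanged.  The CI comes from F = MS_rows / MS_error with
    (n - 1) and (n - 1)(k - 1) degrees of freedom.
    """
    X = _as_matrix(ratings)
    if X.isna().any().any():
        raise ValueError(
            "ICC requires a complete matrix; missing entries present"
        )
    n, k = X.shape
    if n < 3 or k < 2:
        raise ValueError(f"need at least 3 stimuli and 2 raters, got {n} x {k}")
    x = np.asarray(X, dtype=float)
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    ms_rows = ss_rows / df1
    ms_err = ss_err / df2
    if ms_rows == 0:
        raise ValueError(
            "no between-stimulus variance; ICC is undefined (0/0)"
        )
    icc = (ms_rows - ms_err) / ms_rows
    alpha = 1.0 - confidence
    F = ms_rows / ms_err
    f_lo = F / sps.f.ppf(1 - alpha / 2, df1, df2)
    f_hi = F * sps.f.ppf(1 - alpha / 2, df2, df1)
    return ICCResult(
        icc=float(icc),
        ci_lower=float(1 - 1 / f_lo),
        ci_upper=float(1 - 1 / f_hi),
        ms_rows=float(ms_rows),
        ms_error=float(ms_err),
        df1=df1,
        df2=df2,
    )


def pearson(x, y) -> float:
    """Product-moment correlation of two equally long score vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(sps.pearsonr(x, y).statistic)


def williams_t(r12: float, r13: float, r23: float, n: int) -> WilliamsResult:
    """Williams's test for two dependent overlapping correlations.

    Tests r12 = r13 where both correlations share variable 1 and r23 is
    the correlation of the non-shared variables, on n cases:

        t = (r12 - r13) * sqrt( (n-1)(1+r23) /
              ( 2 K (n-1)/(n-3) + rbar^2 (1-r23)^3 ) ),
        K = 1 - r12^2 - r13^2 - r23^2 + 2 r12 r13 r23,
        rbar = (r12 + r13)/2,

    with df = n - 3 and a two-sided p from the t distribution.
    """
    if n <= 3:
        raise ValueError(f"need n > 3, got {n}")
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1 < r < 1:
            raise ValueError(f"{name} must lie strictly in (-1, 1), got {r}")
    K = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    rbar = (r12 + r13) / 2
    denom = 2 * K * (n - 1) / (n - 3) + rbar**2 * (1 - r23) ** 3
    t = (r12 - r13) * math.sqrt((n - 1) * (1 + r23) / denom)
    df = n - 3
    p = 2 * sps.t.sf(abs(t), df)
    return WilliamsResult(t=float(t), df=df, p=float(p))


def rater_subset(data, fraction: float):
    """Keep the data of the first ceil(fraction * R) raters.

    Rater order is first appearance for a :class:`TrialSequence` and
    column order for a ratings matrix.  Typical fractions are 1, 1/2 and
    1/4 (full, half and quarter panels).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if isinstance(data, TrialSequence):
        raters = data.raters
        if not raters:
            raise ValueError("no raters present")
        keep = raters[: math.ceil(fraction * len(raters))]
        return data.subset_raters(keep)
    if isinstance(data, pd.DataFrame):
        if data.shape[1] == 0:
            raise ValueError("no raters present")
        n_keep = math.ceil(fraction * data.shape[1])
        return data.iloc[:, :n_keep]
    raise TypeError("expected a TrialSequence or a stimuli x raters DataFrame")


def summarize(scores) -> MeasureSummary:
    """Mean, sample SD, median, min and max of a score vector."""
    x = np.asarray(scores, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty vector")
    return MeasureSummary(
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        median=float(np.median(x)),
        minimum=float(x.min()),
        maximum=float(x.max()),
    )
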