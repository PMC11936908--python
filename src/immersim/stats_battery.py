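"""Descriptive and inferential test battery for store comparisons.

Implements the classical tests used to compare the two store arms (WS:
women's clothing, MS: men's clothing): pooled-variance Student's t for
means, 2x2 chi-squared for proportions, Pearson correlation, and the
two-sample Kolmogorov-Smirnov test.  The t-test accepts either raw samples
or (n, mean, sd) summaries so published summary tables can be checked
mechanically without the underlying data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

Tails = Literal["one", "two"]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics (n, mean, sd) for one group of a mean comparison."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    tails: Tails = "two"
    estimate: float | None = None  # e.g. Pearson r


GroupLike = Union[GroupSummary, Sequence[float], np.ndarray]


def _as_summary(g: GroupLike) -> GroupSummary:
    if isinstance(g, GroupSummary):
        return g
    x = np.asarray(g, dtype=float)
    return GroupSummary(n=len(x), mean=float(x.mean()), sd=float(np.std(x, ddof=1)))


def pooled_t_test(a: GroupLike, b: GroupLike, tails: Tails = "two") -> TestResult:
    """Pooled-variance two-sample Student's t-test.

    Works from raw samples or from (n, mean, sd) summaries, and gives
    identical answers for a raw sample and its summary.  One-tailed
    p-values are half the two-tailed p, in the direction of the observed
    sign.
    """
    sa, sb = _as_summary(a), _as_summary(b)
    df = sa.n + sb.n - 2
    sp2 = ((sa.n - 1) * sa.sd**2 + (sb.n - 1) * sb.sd**2) / df
    se = np.sqrt(sp2 * (1.0 / sa.n + 1.0 / sb.n))
    if se == 0:
        t = 0.0 if sa.mean == sb.mean else np.inf * np.sign(sa.mean - sb.mean)
    else:
        t = (sa.mean - sb.mean) / se
    p_two = 2.0 * stats.t.sf(abs(t), df)
    p = p_two / 2.0 if tails == "one" else p_two
    return TestResult(statistic=float(t), df=float(df), p_value=float(min(p, 1.0)), tails=tails)


def two_proportion_chi2(
    x_a: int, n_a: int, x_b: int, n_b: int, yates: bool = False
) -> TestResult:
    """Chi-squared test on a 2x2 table of successes/failures, df = 1."""
    if not (0 <= x_a <= n_a and 0 <= x_b <= n_b) or n_a == 0 or n_b == 0:
        raise ValueError("invalid counts")
    table = np.array([[x_a, n_a - x_a], [x_b, n_b - x_b]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in 2x2 table")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=yates)
    return TestResult(statistic=float(chi2), df=float(df), p_value=float(p))


def pearson_correlation(x: Sequence[float], y: Sequence[float], tails: Tails = "two") -> TestResult:
    """Pearson r with its t-statistic t = r*sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a sample")
    r = float(stats.pearsonr(x, y).statistic)
    n = len(x)
    df = n - 2
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = 2.0 * stats.t.sf(abs(t), df)
    if tails == "one":
        p /= 2.0
    return TestResult(statistic=float(t), df=float(df), p_value=float(p), tails=tails, estimate=r)


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (max ECDF gap, asymptotic p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5 or len(y) < 5:
        raise ValueError("need >= 5 observations per sample")
    res = stats.ks_2samp(x, y, method="asymp")
    return TestResult(statistic=float(res.statistic), df=np.nan, p_value=float(res.pvalue))


def summary_battery(summaries: pd.DataFrame) -> pd.DataFrame:
    """Batch pooled t-tests from a table of group summaries.

    ``summaries`` has columns ``label, group, n, mean, sd`` with exactly two
    groups per label; returns one row per label with t, df and p.
    """
    required = {"label", "group", "n", "mean", "sd"}
    if not required.issubset(summaries.columns):
        raise ValueError(f"summary table must have columns {sorted(required)}")
    rows = []
    for label, grp in summaries.groupby("label", sort=False):
        if len(grp) != 2:
            raise ValueError(f"label {label!r} must have exactly two groups")
        g1, g2 = (GroupSummary(int(r.n), float(r.mean), float(r.sd)) for r in grp.itertuples())
        res = pooled_t_test(g1, g2)
        rows.append(
            {
                "label": label,
                "group_a": grp["group"].iloc[0],
                "group_b": grp["group"].iloc[1],
                "t": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)
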