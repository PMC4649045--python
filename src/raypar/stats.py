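"""Statistical analyses of ray metrics: inter-annual variability (CV and
mean sensitivity), Pearson correlation matrices, paired comparisons and
allometric regressions.

The test statistics are computed from their textbook formulas with
p-values from scipy's t distribution; significance markers follow the
conventional thresholds (0.001, 0.01, 0.05, 0.1), with no multiple-testing
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import TimeSeries

__all__ = [
    "StatResult",
    "mean_sensitivity",
    "coefficient_of_variation",
    "pearson_corr",
    "pearson_matrix",
    "paired_t_test",
    "fit_allometry",
    "significance_marker",
    "StatsError",
]


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class StatResult:
    """A statistic with its p-value and auxiliary estimates."""

    statistic: float
    p_value: Optional[float]
    n: int
    name: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise StatsError(f"p-value out of [0, 1]: {self.p_value}")

    def __getattr__(self, item):
        try:
            return self.__dict__["extras"][item]
        except KeyError as exc:  # pragma: no cover
            raise AttributeError(item) from exc


def significance_marker(p: float) -> str:
    """Conventional marker: *** <=0.001, ** <=0.01, * <=0.05, · <=0.1, ns."""
    for thresh, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "·")):
        if p <= thresh:
            return mark
    return "ns"


def _values(series) -> np.ndarray:
    if isinstance(series, TimeSeries):
        return np.asarray(series.values, dtype=float)
    return np.asarray(series, dtype=float)


def mean_sensitivity(series: Union[TimeSeries, np.ndarray]) -> float:
    """Mean sensitivity (%): the average absolute relative change between
    consecutive annual values,

        MS = 100 * mean_t | 2 (x_t - x_{t-1}) / (x_t + x_{t-1}) |.

    Requires at least two strictly positive values.
    """
    x = _values(series)
    if len(x) < 2:
        raise StatsError("mean sensitivity needs a series of length >= 2")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise StatsError("mean sensitivity requires strictly positive, finite values")
    steps = np.abs(2.0 * np.diff(x) / (x[1:] + x[:-1]))
    return 100.0 * float(steps.mean())


def coefficient_of_variation(sample: Union[TimeSeries, np.ndarray]) -> float:
    """Sample CV: sd (n-1 denominator) over mean."""
    x = _values(sample)
    if len(x) < 2:
        raise StatsError("CV needs at least 2 values")
    m = x.mean()
    if m == 0:
        raise StatsError("CV undefined for zero mean")
    return float(x.std(ddof=1) / m)


def pearson_corr(x, y) -> StatResult:
    """Pearson r with a two-sided p from the t distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise StatsError("Pearson correlation needs two equal samples of length >= 3")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        return StatResult(statistic=np.nan, p_value=None, n=n, name="pearson", extras={"degenerate": True})
    r = float(np.sum((x - x.mean()) * (y - y.mean())) / ((n - 1) * sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return StatResult(statistic=r, p_value=p, n=n, name="pearson", extras={"degenerate": False})


def pearson_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation matrix of a tidy metric table.

    Returns (r, p) DataFrames; the diagonal holds r = 1, p = 0.  A
    zero-variance column yields NaN r and p (flagged, not silently 0).
    Rows with any missing value are dropped (complete-case).
    """
    df = table.dropna()
    if len(df) < 3:
        raise StatsError("correlation matrix needs >= 3 complete rows")
    cols = df.columns
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            res = pearson_corr(df[a].to_numpy(), df[b].to_numpy())
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = np.nan if res.p_value is None else res.p_value
    return r, p


def paired_t_test(a, b, paired: bool = True) -> StatResult:
    """Two-sided t test comparing samples a and b.

    Paired by default (the natural structure for tree x ring values
    measured in both conditions); ``paired=False`` falls back to Welch's
    two-sample test.  The sign convention is t > 0 when mean(a) > mean(b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b) or len(a) < 2:
            raise StatsError("paired test needs two equal-length samples of length >= 2")
        d = a - b
        sd = d.std(ddof=1)
        n = len(d)
        if sd == 0:
            if np.all(d == 0):  # identical samples: no effect, no evidence
                return StatResult(
                    statistic=0.0,
                    p_value=1.0,
                    n=n,
                    name="paired_t",
                    extras={"mean_a": float(a.mean()), "mean_b": float(b.mean()), "mean_diff": 0.0, "df": n - 1},
                )
            raise StatsError("constant non-zero paired differences: t undefined")
        t = float(d.mean() / (sd / math.sqrt(n)))
        p = 2.0 * float(sps.t.sf(abs(t), n - 1))
        extras = {"mean_a": float(a.mean()), "mean_b": float(b.mean()), "mean_diff": float(d.mean()), "df": n - 1}
        return StatResult(statistic=t, p_value=p, n=n, name="paired_t", extras=extras)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("two-sample test needs >= 2 values per sample")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    extras = {"mean_a": float(a.mean()), "mean_b": float(b.mean())}
    return StatResult(statistic=float(t), p_value=float(p), n=len(a) + len(b), name="welch_t", extras=extras)


def fit_allometry(x, y) -> StatResult:
    """Ordinary least squares of y on x with R^2 = 1 - SSres/SStot.

    Used for the allometric relationships between individual ray area and
    ray length (cross/radial planes) or ray height (tangential plane).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise StatsError("allometric fit needs two equal samples of length >= 3")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise StatsError("constant x: slope undefined")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sstot == 0 else 1.0 - float(np.sum(resid**2)) / sstot
    # two-sided p for the slope from its t statistic (n-2 df)
    if n > 2 and sstot > 0 and r2 < 1.0:
        se = math.sqrt(float(np.sum(resid**2)) / (n - 2) / sxx)
        t = slope / se if se > 0 else math.inf
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    else:
        t, p = math.inf, 0.0
    return StatResult(
        statistic=t,
        p_value=p,
        n=n,
        name="ols",
        extras={"slope": slope, "intercept": intercept, "r_squared": r2},
    )
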