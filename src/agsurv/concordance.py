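"""Concordance statistics between the dispensing signal and sentinel data.

The two weekly indicators live on different scales — episode counts
within an unknown drugstore-panel population versus estimated national
incidence — so agreement statistics (intraclass correlation, Bland-
Altman) do not apply.  Concordance is therefore assessed with:

* Pearson correlation with a Fisher-z 95% confidence interval, at no
  lag and at one-week lag/lead (to absorb dispensing postponement and
  sentinel reporting-window imputation);
* a linearity check: linear regression versus a natural cubic spline
  with 3 interior knots, compared by a nested-model F test;
* slope-heterogeneity across subgroups (age groups or regions): OLS
  with stratum main effects and stratum-by-slope interactions, F test
  on the interaction block;
* weekly detection rates (100 x algorithm count / sentinel count) with
  median and quartiles, and the peak-week comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from patsy import dmatrix
from scipy import stats

from .weeks import WeeklySeries

logger = logging.getLogger(__name__)

SeriesLike = Union[WeeklySeries, Sequence[float]]


def _values(x: SeriesLike) -> np.ndarray:
    if isinstance(x, WeeklySeries):
        return np.asarray(x.values, dtype=float)
    return np.asarray(x, dtype=float)


def _weeks(x: SeriesLike):
    return list(x.window.weeks) if isinstance(x, WeeklySeries) else None


@dataclass(frozen=True)
class CorrelationEstimate:
    r: float
    ci_low: float
    ci_high: float
    n: int
    lag: int = 0

    def rounded(self, ndigits: int = 2) -> Tuple[float, float, float]:
        return (round(self.r, ndigits), round(self.ci_low, ndigits), round(self.ci_high, ndigits))


@dataclass(frozen=True)
class LinearityTest:
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    knots: Tuple[float, ...]


@dataclass(frozen=True)
class HeterogeneityTest:
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    grouping: str


@dataclass(frozen=True)
class RateSummary:
    weekly_rates: Tuple[float, ...]
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class PeakComparison:
    peak_week_algorithm: Tuple[int, int]
    peak_week_sentinel: Tuple[int, int]
    match: bool


def fisher_ci(r: float, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Fisher z-transform confidence interval: tanh(atanh(r) +- z/sqrt(n-3))."""
    if n < 4:
        raise ValueError("Fisher interval requires n >= 4")
    if abs(r) >= 1.0:
        return (r, r)  # degenerate at perfect correlation
    z = stats.norm.ppf(0.5 + level / 2)
    zr = math.atanh(r)
    half = z / math.sqrt(n - 3)
    return (math.tanh(zr - half), math.tanh(zr + half))


def pearson_with_ci(x: SeriesLike, y: SeriesLike, level: float = 0.95, lag: int = 0) -> CorrelationEstimate:
    xv, yv = _values(x), _values(y)
    if xv.shape != yv.shape:
        raise ValueError("series must have equal length")
    n = xv.size
    if n < 4:
        raise ValueError("need at least 4 weekly pairs")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("correlation undefined for a zero-variance series")
    r = float(stats.pearsonr(xv, yv).statistic)
    lo, hi = fisher_ci(r, n, level)
    return CorrelationEstimate(r=r, ci_low=lo, ci_high=hi, n=n, lag=lag)


def lagged_correlations(
    x: SeriesLike, y: SeriesLike, level: float = 0.95
) -> Dict[int, CorrelationEstimate]:
    """Correlations at lags -1, 0, +1 of x (algorithm) against y (sentinel).

    Lag +1 pairs the algorithm series at week n+1 with the sentinel
    series at week n (dispensing postponed); lag -1 pairs week n with
    sentinel week n+1 (sentinel reporting postponed).
    """
    xv, yv = _values(x), _values(y)
    if xv.shape != yv.shape:
        raise ValueError("series must have equal length")
    out = {}
    for lag in (-1, 0, 1):
        if lag == 0:
            xs, ys = xv, yv
        elif lag == 1:
            xs, ys = xv[1:], yv[:-1]
        else:
            xs, ys = xv[:-1], yv[1:]
        out[lag] = pearson_with_ci(xs, ys, level=level, lag=lag)
    return out


def _natural_spline_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Natural cubic regression spline basis (with intercept column)."""
    basis = dmatrix(
        "cr(x, knots=knots)", {"x": x, "knots": tuple(knots)}, return_type="matrix"
    )
    return np.asarray(basis)


def _ols_rss(design: np.ndarray, y: np.ndarray) -> Tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid), int(rank)


def _nested_f(rss_reduced: float, rss_full: float, df_num: int, df_den: int, scale: float):
    """F statistic and p-value for nested OLS models.

    A numerically zero full-model RSS (both fits interpolate, e.g. data
    exactly on a line) carries no evidence against the reduced model:
    F = 0, p = 1.
    """
    if rss_full <= 1e-12 * max(scale, 1.0):
        return 0.0, 1.0
    f = max(rss_reduced - rss_full, 0.0) / df_num / (rss_full / df_den)
    return float(f), float(stats.f.sf(f, df_num, df_den))


def linearity_test(
    x: SeriesLike, y: SeriesLike, knots: Optional[Sequence[float]] = None
) -> LinearityTest:
    """Nested F test: linear model vs natural cubic spline in x.

    Knots default to the 25th/50th/75th percentiles of x.  A small F
    (p near 1) means the spline adds nothing — the linear description
    of the relation suffices.
    """
    xv, yv = _values(x), _values(y)
    n = xv.size
    if n < 10:
        raise ValueError("linearity test requires n >= 10")
    if np.unique(xv).size < 5:
        raise ValueError("x has too few distinct values for a spline fit")
    if knots is None:
        knots = tuple(np.percentile(xv, [25, 50, 75]))
    knots = tuple(float(k) for k in knots)

    lin = np.column_stack([np.ones(n), xv])
    spl = _natural_spline_basis(xv, knots)
    rss_lin, rank_lin = _ols_rss(lin, yv)
    rss_spl, rank_spl = _ols_rss(spl, yv)
    df_num = rank_spl - rank_lin
    df_den = n - rank_spl
    if df_num <= 0 or df_den <= 0:
        raise ValueError("degenerate design for linearity test")
    f, p = _nested_f(rss_lin, rss_spl, df_num, df_den, float(yv @ yv))
    return LinearityTest(f_stat=f, df_num=df_num, df_den=df_den, p_value=p, knots=knots)


def heterogeneity_test(
    pairs: Dict[str, Tuple[SeriesLike, SeriesLike]], grouping: str = "age"
) -> HeterogeneityTest:
    """F test for slope differences across strata.

    Fits algorithm counts on sentinel counts with stratum intercepts and
    stratum-specific slopes (full model) versus a common slope (reduced
    model); the F test compares the two.  Strata whose sentinel series
    has zero variance are dropped with a warning.
    """
    usable: List[Tuple[np.ndarray, np.ndarray]] = []
    for name, (xs, ys) in pairs.items():
        yv = _values(ys)  # sentinel (predictor)
        xv = _values(xs)  # algorithm counts (response)
        if np.ptp(yv) == 0:
            logger.warning("stratum %r has zero-variance sentinel series; excluded", name)
            continue
        usable.append((xv, yv))
    k = len(usable)
    if k < 2:
        raise ValueError("heterogeneity test requires >= 2 usable strata")

    resp = np.concatenate([xv for xv, _ in usable])
    n = resp.size
    full = np.zeros((n, 2 * k))
    reduced = np.zeros((n, k + 1))
    row = 0
    for j, (xv, yv) in enumerate(usable):
        m = xv.size
        sl = slice(row, row + m)
        full[sl, j] = 1.0
        full[sl, k + j] = yv
        reduced[sl, j] = 1.0
        reduced[sl, k] = yv
        row += m

    rss_red, rank_red = _ols_rss(reduced, resp)
    rss_full, rank_full = _ols_rss(full, resp)
    df_num = rank_full - rank_red
    df_den = n - rank_full
    if df_num <= 0 or df_den <= 0:
        raise ValueError("degenerate design for heterogeneity test")
    f, p = _nested_f(rss_red, rss_full, df_num, df_den, float(resp @ resp))
    return HeterogeneityTest(f, df_num, df_den, p, grouping)


def weekly_rates(x: SeriesLike, y: SeriesLike) -> RateSummary:
    """Per-week 100*x/y with median and quartiles; zero-sentinel weeks dropped."""
    xv, yv = _values(x), _values(y)
    if xv.shape != yv.shape:
        raise ValueError("series must have equal length")
    keep = yv > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropping %d weeks with zero sentinel count", dropped)
    if not keep.any():
        raise ValueError("no weeks with positive sentinel count")
    rates = 100.0 * xv[keep] / yv[keep]
    q1, med, q3 = np.percentile(rates, [25, 50, 75])
    return RateSummary(tuple(float(r) for r in rates), float(med), float(q1), float(q3))


def peak_comparison(x: WeeklySeries, y: WeeklySeries) -> PeakComparison:
    """Compare argmax weeks of the two aligned series (ties -> earliest week)."""
    if x.window.weeks != y.window.weeks:
        raise ValueError("series must share the same window")
    xv, yv = _values(x), _values(y)
    ix, iy = int(np.argmax(xv)), int(np.argmax(yv))
    for name, v, i in (("algorithm", xv, ix), ("sentinel", yv, iy)):
        if (v == v[i]).sum() > 1:
            logger.warning("%s series has a tied peak; using the earliest week", name)
    wx, wy = x.window.weeks[ix], y.window.weeks[iy]
    return PeakComparison(wx, wy, wx == wy)
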