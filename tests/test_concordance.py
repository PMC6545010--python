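import numpy as np
import pytest
from scipy import stats

from agsurv.concordance import (
    fisher_ci,
    heterogeneity_test,
    lagged_correlations,
    linearity_test,
    peak_comparison,
    pearson_with_ci,
    weekly_rates,
)
from agsurv.weeks import WeeklySeries, winter_window


# ------------------------------------------------------------- Pearson + CI
def test_perfect_linear_relation_gives_r_one_with_collapsed_ci():
    x = np.arange(32, dtype=float)
    est = pearson_with_ci(x, 2 * x + 3)
    assert est.r == pytest.approx(1.0)
    assert est.ci_low == est.ci_high == pytest.approx(1.0)


def test_fisher_ci_matches_scipy_reference():
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=(2, 40))
    est = pearson_with_ci(x, y)
    ref = stats.pearsonr(x, y).confidence_interval()
    assert est.ci_low == pytest.approx(ref.low, abs=1e-10)
    assert est.ci_high == pytest.approx(ref.high, abs=1e-10)


def test_fisher_ci_bounds_stay_inside_unit_interval():
    for r in (-0.999, -0.5, 0.0, 0.5, 0.999):
        lo, hi = fisher_ci(r, 20)
        assert -1 < lo <= r <= hi < 1


def test_ci_coverage_under_independence():
    """Monte-Carlo: the 95% Fisher CI covers rho=0 in ~95% of replicates."""
    rng = np.random.default_rng(11)
    n, reps = 30, 10_000
    x = rng.normal(size=(reps, n))
    y = rng.normal(size=(reps, n))
    xc = x - x.mean(1, keepdims=True)
    yc = y - y.mean(1, keepdims=True)
    r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    covered = (np.tanh(np.arctanh(r) - half) <= 0) & (0 <= np.tanh(np.arctanh(r) + half))
    assert 0.94 <= covered.mean() <= 0.96


def test_correlation_is_symmetric_and_affine_invariant():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=(2, 32))
    a = pearson_with_ci(x, y)
    b = pearson_with_ci(y, x)
    assert a.r == pytest.approx(b.r) and a.ci_low == pytest.approx(b.ci_low)
    c = pearson_with_ci(3.0 * x + 7.0, y)
    assert c.r == pytest.approx(a.r)


def test_zero_variance_series_is_an_error():
    with pytest.raises(ValueError, match="zero-variance"):
        pearson_with_ci(np.ones(10), np.arange(10.0))


def test_short_series_is_an_error():
    with pytest.raises(ValueError, match="4"):
        pearson_with_ci(np.arange(3.0), np.arange(3.0))


# ------------------------------------------------------------------- lagging
def test_shifted_series_peaks_at_lag_plus_one():
    rng = np.random.default_rng(8)
    base = np.convolve(rng.normal(size=40), np.ones(5) / 5, mode="same")
    x, y = base[0:32], base[1:33]  # x runs one week late relative to y
    by_lag = lagged_correlations(x, y)
    assert by_lag[1].r == max(est.r for est in by_lag.values())
    assert by_lag[1].n == 31  # one week lost to the shift


def test_identical_series_correlate_perfectly_at_lag_zero():
    x = np.sin(np.linspace(0, 3, 32)) + 2
    assert lagged_correlations(x, x)[0].r == pytest.approx(1.0)


def test_white_noise_rarely_exceeds_moderate_correlation():
    rng = np.random.default_rng(21)
    hits = {-1: 0, 0: 0, 1: 0}
    seeds = 400
    for _ in range(seeds):
        x, y = rng.normal(size=(2, 32))
        for lag, est in lagged_correlations(x, y).items():
            hits[lag] += abs(est.r) < 0.4
    for lag in hits:
        assert hits[lag] / seeds >= 0.95


# ----------------------------------------------------------------- linearity
def test_exactly_linear_data_yields_f_zero():
    x = np.arange(1.0, 33.0)
    res = linearity_test(x, 3.0 * x + 1.0)
    assert res.f_stat == 0.0 and res.p_value == 1.0


def test_strong_curvature_is_detected():
    rng = np.random.default_rng(4)
    x = np.arange(1.0, 33.0)
    y = x**2 + rng.normal(0, 5.0, size=32)
    assert linearity_test(x, y).p_value < 0.01


def test_linearity_matches_statsmodels_anova():
    import statsmodels.api as sm
    from patsy import dmatrix

    rng = np.random.default_rng(9)
    x = rng.uniform(0, 100, size=32)
    y = 2 * x + rng.normal(0, 15, size=32)
    res = linearity_test(x, y)
    lin = sm.OLS(y, np.column_stack([np.ones(32), x])).fit()
    spl = sm.OLS(y, np.asarray(dmatrix("cr(x, knots=k)", {"x": x, "k": res.knots}))).fit()
    table = sm.stats.anova_lm(lin, spl)
    assert res.f_stat == pytest.approx(table["F"][1], rel=1e-8)
    assert res.p_value == pytest.approx(table["Pr(>F)"][1], rel=1e-8)


def test_degenerate_predictor_is_an_error():
    x = np.repeat([1.0, 2.0], 16)
    with pytest.raises(ValueError, match="distinct"):
        linearity_test(x, np.arange(32.0))


# ------------------------------------------------------------- heterogeneity
def test_identical_slopes_without_noise_give_p_one():
    x = np.arange(32.0)
    pairs = {"a": (2 * x + 1, x), "b": (2 * x + 5, x)}
    res = heterogeneity_test(pairs)
    assert res.f_stat == 0.0 and res.p_value == 1.0


def test_different_slopes_are_detected_with_high_power():
    rng = np.random.default_rng(17)
    x = np.linspace(0, 100, 32)
    hits = 0
    for _ in range(100):
        pairs = {
            "a": (1.0 * x + rng.normal(0, 10, 32), x),
            "b": (2.0 * x + rng.normal(0, 10, 32), x),
        }
        hits += heterogeneity_test(pairs).p_value < 0.01
    assert hits >= 90


def test_zero_variance_stratum_is_dropped():
    x = np.arange(32.0)
    rng = np.random.default_rng(2)
    pairs = {
        "a": (x + rng.normal(0, 1, 32), x),
        "b": (2 * x + rng.normal(0, 1, 32), x),
        "flat": (x, np.ones(32)),
    }
    res = heterogeneity_test(pairs)
    assert res.df_num == 1  # two usable strata -> one interaction df


def test_single_usable_stratum_is_an_error():
    x = np.arange(32.0)
    with pytest.raises(ValueError, match="2 usable strata"):
        heterogeneity_test({"a": (x, x), "flat": (x, np.ones(32))})


# -------------------------------------------------------------- rates, peaks
def test_identical_series_rate_is_100():
    x = np.arange(1.0, 33.0)
    rs = weekly_rates(x, x)
    assert rs.median == 100.0 and rs.q1 == 100.0 and rs.q3 == 100.0


def test_scaled_series_rate_matches_scale():
    y = np.arange(1.0, 33.0) * 10
    rs = weekly_rates(0.44 * y, y)
    assert rs.median == pytest.approx(44.0)


def test_zero_sentinel_weeks_are_dropped():
    y = np.array([0.0, 10.0, 20.0, 10.0, 0.0])
    x = np.array([5.0, 5.0, 10.0, 5.0, 9.0])
    rs = weekly_rates(x, y)
    assert len(rs.weekly_rates) == 3


def series(values, stratum="all", year=2016):
    w = winter_window(year)
    vals = list(values) + [0.0] * (len(w) - len(values))
    return WeeklySeries(stratum, w, vals)


def test_peak_comparison_matching_and_shifted():
    x = series([1, 2, 9, 2, 1])
    assert peak_comparison(x, series([2, 3, 7, 3, 2])).match
    shifted = series([9, 1, 1, 1, 1])
    cmp = peak_comparison(x, shifted)
    assert not cmp.match
    assert cmp.peak_week_algorithm == (2016, 38)
    assert cmp.peak_week_sentinel == (2016, 36)


def test_peak_tie_breaks_to_earliest_week(caplog):
    import logging

    x = series([5, 9, 9, 1])
    with caplog.at_level(logging.WARNING):
        cmp = peak_comparison(x, x)
    assert cmp.peak_week_algorithm == (2016, 37)
    assert "tied peak" in caplog.text
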