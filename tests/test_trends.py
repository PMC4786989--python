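"""OLS trends, relative trends, normalization, station comparison."""

import numpy as np
import pytest

from satno2.grid import GridSpec
from satno2.synthetic_world import StationRecord
from satno2.trends import (
    StationRules,
    TrendEstimate,
    compare_with_stations,
    normalize_to_longterm_mean,
    ols_trend,
    subperiod_trend,
    trend_difference,
)


def test_three_point_closed_form():
    """years (0,1,2), values (1,2,4): slope 1.5, mean 7/3, relative 64.3%/yr."""
    est = ols_trend([0, 1, 2], [1.0, 2.0, 4.0])
    assert est.slope == pytest.approx(1.5)
    assert est.longterm_mean == pytest.approx(7 / 3)
    assert est.rel_trend == pytest.approx(100 * 1.5 / (7 / 3))
    assert est.rel_trend == pytest.approx(64.2857, abs=1e-3)


def test_exact_linear_fit_zero_ci_width():
    years = np.arange(1996, 2013)
    est = ols_trend(years, 2.0 + 0.1 * (years - 1996))
    assert est.slope == pytest.approx(0.1)
    assert est.ci[1] - est.ci[0] == pytest.approx(0.0, abs=1e-10)
    assert est.p < 1e-200


def test_constant_series_degenerate_contract():
    est = ols_trend(np.arange(10), np.full(10, 3.0))
    assert est.slope == 0.0 and est.p == 1.0


def test_missing_years_dropped_not_imputed():
    years = np.arange(2000, 2010, dtype=float)
    values = years * 0.5
    values[3] = np.nan
    est = ols_trend(years, values)
    assert est.n == 9
    assert est.slope == pytest.approx(0.5)


def test_too_few_points_signalled():
    with pytest.raises(ValueError):
        ols_trend([2000, 2001], [1.0, 2.0])


def test_matches_statsmodels(rng):
    import statsmodels.api as sm

    years = np.arange(1996, 2013, dtype=float)
    values = 3.0 - 0.05 * (years - 2004) + rng.normal(0, 0.2, years.size)
    est = ols_trend(years, values)
    fit = sm.OLS(values, sm.add_constant(years - years.mean())).fit()
    assert est.slope == pytest.approx(fit.params[1], rel=1e-10)
    assert est.p == pytest.approx(fit.pvalues[1], rel=1e-8)
    lo, hi = fit.conf_int(alpha=0.05)[1]
    assert est.ci == pytest.approx((lo, hi), rel=1e-8)


def test_relative_trend_scale_invariant(rng):
    years = np.arange(1996, 2013, dtype=float)
    values = 2.0 + 0.03 * (years - 2004) + rng.normal(0, 0.1, years.size)
    a = ols_trend(years, values)
    b = ols_trend(years, 17.3 * values)
    assert a.rel_trend == pytest.approx(b.rel_trend, rel=1e-10)
    assert a.rel_ci == pytest.approx(b.rel_ci, rel=1e-10)


def test_significance_boundary_inclusive():
    est = TrendEstimate(1.0, (0.5, 1.5), 0.01, 2.0, 50.0, (25.0, 75.0), 17, (1996, 2012))
    assert est.significant(0.01)  # p == alpha counts under "alpha <= 0.01"
    est2 = TrendEstimate(1.0, (0.5, 1.5), 0.0101, 2.0, 50.0, (25.0, 75.0), 17, (1996, 2012))
    assert not est2.significant(0.01)


def test_ci_coverage_nominal(rng):
    """Across 200 white-noise series with a known slope, the 95% CI covers
    the truth at 95% +/- 4%."""
    years = np.arange(1996, 2013, dtype=float)
    true_slope = 0.05
    hits = 0
    n = 200
    for _ in range(n):
        values = 2.0 + true_slope * (years - 2004) + rng.normal(0, 0.15, years.size)
        est = ols_trend(years, values)
        hits += est.ci[0] <= true_slope <= est.ci[1]
    assert 0.91 <= hits / n <= 0.99


# ----------------------------------------------------------------------
# sub-periods and normalization
# ----------------------------------------------------------------------
def test_subperiod_equals_full_when_identical():
    years = np.arange(1996, 2013, dtype=float)
    values = 3.0 - 0.04 * (years - 2004)
    a = ols_trend(years, values)
    b = subperiod_trend(years, values, 1996, 2012)
    assert a.slope == pytest.approx(b.slope)
    assert a.rel_trend == pytest.approx(b.rel_trend)


def test_subperiod_uses_full_period_mean():
    """Piecewise-linear series: sub-slopes verified by direct OLS, relative
    trends divided by the full-record mean."""
    years = np.arange(1996, 2013, dtype=float)
    values = np.where(years <= 2003, 10.0 - 0.1 * (years - 1996),
                      9.3 - 0.5 * (years - 2003))
    full_mean = values.mean()
    for (a, b) in [(1996, 2003), (2004, 2010)]:
        est = subperiod_trend(years, values, a, b)
        sel = (years >= a) & (years <= b)
        slope_direct = np.polyfit(years[sel], values[sel], 1)[0]
        assert est.slope == pytest.approx(slope_direct, rel=1e-10)
        assert est.rel_trend == pytest.approx(100 * slope_direct / full_mean, rel=1e-10)
        assert est.longterm_mean == pytest.approx(full_mean)


def test_subperiod_outside_series_rejected():
    years = np.arange(2000, 2010, dtype=float)
    with pytest.raises(ValueError):
        subperiod_trend(years, years * 0.1, 1990, 1995)


def test_normalize_to_longterm_mean():
    out = normalize_to_longterm_mean([0, 1], [1.0, 3.0])
    np.testing.assert_allclose(out.values, [0.5, 1.5])
    assert out.values.mean() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        normalize_to_longterm_mean([0, 1], [1.0, -3.0])


def test_normalization_preserves_relative_trend(rng):
    years = np.arange(1996, 2013, dtype=float)
    values = 2.0 + 0.03 * (years - 2004) + rng.normal(0, 0.1, years.size)
    norm = normalize_to_longterm_mean(years, values)
    a = ols_trend(years, values)
    b = ols_trend(norm.years, norm.values)
    assert a.rel_trend == pytest.approx(b.rel_trend, rel=1e-10)


@pytest.mark.parametrize("a, b, expected", [(-4.4, -3.7, 0.7), (-2.2, -1.9, 0.3),
                                            (1.5, 1.5, 0.0)])
def test_trend_difference(a, b, expected):
    assert trend_difference(a, b) == pytest.approx(expected)


# ----------------------------------------------------------------------
# station comparison
# ----------------------------------------------------------------------
def _toy_world(nyears=17, ndays=6):
    grid = GridSpec(30.0, 0.0, 3, 3)
    years = tuple(range(1996, 1996 + nyears))
    doys = np.arange(1, 1 + 5 * ndays, 5)
    # truth at every cell declines 3%/year
    base = np.array([(0.97**k) for k in range(nyears)])
    values = np.tile(base[:, None], (1, ndays)) * 2.0
    surface = np.tile(base[:, None, None], (1, 3, 3)) * 2.0
    masks = {y: np.ones((ndays, 3, 3), dtype=bool) for y in years}
    return grid, years, doys, values, surface, masks


def _station(lat, lon, cls, bias, years, doys, values):
    return StationRecord(lat, lon, cls, bias, years, doys, values * bias)


def test_biased_station_trend_difference_vanishes():
    grid, years, doys, values, surface, masks = _toy_world()
    st = _station(30.05, 0.05, "urban", 1.3, years, doys, values)
    df = compare_with_stations(list(years), surface, grid, [st], masks)
    assert len(df) == 1
    assert df["trend_difference"].iloc[0] == pytest.approx(0.0, abs=1e-9)


def test_station_with_too_few_years_excluded():
    grid, years, doys, values, surface, masks = _toy_world()
    st = _station(30.05, 0.05, "urban", 1.0, years, doys, values)
    short = {y: m if y < years[14] else np.zeros_like(m)
             for y, m in masks.items()}  # only 14 coincident years
    df = compare_with_stations(list(years), surface, grid, [st], short)
    assert df.empty


def test_traffic_class_excluded_others_kept():
    grid, years, doys, values, surface, masks = _toy_world()
    stations = [
        _station(30.05 + 0.1 * i, 0.05, cls, 1.0, years, doys, values)
        for i, cls in enumerate(["traffic", "urban", "rural"])
    ]
    df = compare_with_stations(list(years), surface, grid, stations, masks)
    assert len(df) == 2
    df2 = compare_with_stations(list(years), surface, grid, stations, masks,
                                StationRules(exclude_traffic=False))
    assert len(df2) == 3


def test_same_pixel_stations_averaged():
    grid, years, doys, values, surface, masks = _toy_world()
    stations = [_station(30.05, 0.05, "urban", b, years, doys, values)
                for b in (0.8, 1.0, 1.2)]
    df = compare_with_stations(list(years), surface, grid, stations, masks)
    assert len(df) == 1 and df["n_stations"].iloc[0] == 3
    # averaging biased copies of one series leaves the relative trend intact
    assert df["trend_difference"].iloc[0] == pytest.approx(0.0, abs=1e-9)


def test_coincidence_rule_counts_min_five_per_year():
    grid, years, doys, values, surface, masks = _toy_world(ndays=6)
    st = _station(30.05, 0.05, "urban", 1.0, years, doys, values)
    sparse = {y: m.copy() for y, m in masks.items()}
    for y in years:
        sparse[y][4:, :, :] = False  # only 4 coincident days per year
    df = compare_with_stations(list(years), surface, grid, [st], sparse)
    assert df.empty
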