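"""OLS trend estimation and relative-trend comparison with stations.

Trends are ordinary least squares on annual means, with 95% confidence
intervals from the t distribution on n-2 degrees of freedom, and are
reported in percent/year relative to the series long-term mean (the
same transform applied to the CI ends).  Significance is classified at
alpha <= 0.01 inclusive.  Years are centred before fitting for
numerical stability; no autocorrelation correction is applied by
default (a Newey-West flag exists for sensitivity checks only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_world import StationRecord

__all__ = [
    "TrendEstimate",
    "NormalizedSeries",
    "StationRules",
    "ols_trend",
    "subperiod_trend",
    "normalize_to_longterm_mean",
    "trend_difference",
    "compare_with_stations",
    "trend_table",
]


@dataclass
class TrendEstimate:
    """Slope with uncertainty, absolute [ppb/year] and relative [%/year]."""

    slope: float
    ci: tuple[float, float]
    p: float
    longterm_mean: float
    rel_trend: float
    rel_ci: tuple[float, float]
    n: int
    period: tuple[int, int]

    def significant(self, alpha: float = 0.01) -> bool:
        """alpha <= 0.01 convention: p equal to alpha counts."""
        return bool(self.p <= alpha)


@dataclass
class NormalizedSeries:
    """Series divided by its own long-term mean (mean of the result is 1)."""

    years: np.ndarray
    values: np.ndarray


def _clean(years, values):
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    return years[ok], values[ok]


def ols_trend(years, values, period: tuple[int, int] | None = None,
              longterm_mean: float | None = None,
              newey_west: bool = False) -> TrendEstimate:
    """Least-squares linear trend of an annual series.

    Missing (NaN) years are dropped, not imputed; at least 3 points are
    required.  ``CI = slope +/- t(0.975, n-2) * SE``; the two-sided p
    comes from the t test on the slope.  A zero-residual, zero-slope
    (constant) series gets p = 1 by convention; an exact nonconstant fit
    gets SE 0 and p 0.  ``longterm_mean`` overrides the mean used for
    the relative trend (for sub-period trends referenced to the full
    record).  ``newey_west`` swaps in HAC standard errors (statsmodels)
    for sensitivity analyses.
    """
    years, values = _clean(years, values)
    if period is not None:
        sel = (years >= period[0]) & (years <= period[1])
        years, values = years[sel], values[sel]
    n = years.size
    if n < 3:
        raise ValueError(f"need >= 3 non-missing years, got {n}")
    t = years - years.mean()
    stt = float(np.sum(t * t))
    slope = float(np.sum(t * values) / stt)
    intercept = float(values.mean())
    resid = values - (intercept + slope * t)
    sse = float(np.sum(resid**2))
    dof = n - 2
    if newey_west:
        import statsmodels.api as sm

        x = sm.add_constant(t)
        fit = sm.OLS(values, x).fit(cov_type="HAC", cov_kwds={"maxlags": 1})
        se = float(fit.bse[1])
    else:
        se = float(np.sqrt(sse / dof / stt))
    tcrit = float(stats.t.ppf(0.975, dof))
    ci = (slope - tcrit * se, slope + tcrit * se)
    if se == 0:
        p = 1.0 if slope == 0 else 0.0
    else:
        p = float(2 * stats.t.sf(abs(slope) / se, dof))
    mean = float(values.mean()) if longterm_mean is None else float(longterm_mean)
    if mean == 0:
        rel, rel_ci = float("nan"), (float("nan"), float("nan"))
    else:
        rel = 100.0 * slope / mean
        rel_ci = (100.0 * ci[0] / mean, 100.0 * ci[1] / mean)
    return TrendEstimate(slope, ci, p, mean, rel, rel_ci, n,
                         (int(years.min()), int(years.max())))


def subperiod_trend(years, values, start: int, end: int) -> TrendEstimate:
    """Trend fitted on a sub-period, expressed in %/year of the FULL
    record's long-term mean (the convention for reporting accelerations
    within a longer record)."""
    yc, vc = _clean(years, values)
    if not (yc.min() <= start <= end <= yc.max()):
        raise ValueError("sub-period must lie within the series period")
    full_mean = float(vc.mean())
    return ols_trend(yc, vc, period=(start, end), longterm_mean=full_mean)


def normalize_to_longterm_mean(years, values) -> NormalizedSeries:
    """Divide by the mean over the series' own non-missing years."""
    yc, vc = _clean(years, values)
    mean = float(vc.mean())
    if mean <= 0:
        raise ValueError("long-term mean must be positive to normalize")
    return NormalizedSeries(yc, vc / mean)


def trend_difference(rel_trend_a: float, rel_trend_b: float) -> float:
    """Absolute difference of two relative trends [%/year]."""
    return abs(rel_trend_a - rel_trend_b)


# ----------------------------------------------------------------------
# station comparison
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class StationRules:
    """Station selection: >= min_coincident satellite-coincident
    observations per year, >= min_years such years, traffic sites
    excluded (they represent street canyons, not 0.1-degree cells)."""

    min_coincident: int = 5
    min_years: int = 15
    exclude_traffic: bool = True


def station_passes(station: StationRecord, coincident_per_year: np.ndarray,
                   rules: StationRules) -> bool:
    if rules.exclude_traffic and station.site_class == "traffic":
        return False
    return int((coincident_per_year >= rules.min_coincident).sum()) >= rules.min_years


def compare_with_stations(
    surface_years: list[int],
    surface_fields: np.ndarray,
    grid,
    stations: list[StationRecord],
    valid_masks: dict[int, np.ndarray],
    rules: StationRules | None = None,
) -> pd.DataFrame:
    """Relative-trend comparison of the satellite record against stations.

    Stations are filtered by ``rules`` (coincidence counted against the
    per-year (ndays, nlat, nlon) retrieval masks); stations sharing a
    pixel are averaged; the pixel and station annual series are each
    normalized to their own long-term means and their OLS relative
    trends differenced.  Station annual means use all station days
    (completely sampled ground averages).  Returns one row per pixel;
    empty result (no station passes) is signalled with an empty frame.
    """
    rules = rules or StationRules()
    by_pixel: dict[tuple[int, int], list[StationRecord]] = {}
    for st in stations:
        i, j = grid.locate(st.lat, st.lon)
        coincident = np.array([
            valid_masks[y][:, i, j].sum() if y in valid_masks else 0
            for y in surface_years
        ])
        if station_passes(st, coincident, rules):
            by_pixel.setdefault((i, j), []).append(st)
    rows = []
    for (i, j), group in sorted(by_pixel.items()):
        station_annual = np.mean(
            [st.values.mean(axis=1) for st in group], axis=0
        )  # averaged over same-pixel stations, then over days
        st_years = np.array(group[0].years)
        sat = surface_fields[:, i, j]
        ok = ~np.isnan(sat)
        if ok.sum() < 3:
            continue
        sat_trend = ols_trend(np.array(surface_years)[ok], sat[ok])
        sel = np.isin(st_years, np.array(surface_years))
        ground_trend = ols_trend(st_years[sel], station_annual[sel])
        rows.append({
            "pixel_i": i, "pixel_j": j, "n_stations": len(group),
            "sat_rel_trend": sat_trend.rel_trend,
            "sat_rel_ci_lo": sat_trend.rel_ci[0],
            "sat_rel_ci_hi": sat_trend.rel_ci[1],
            "ground_rel_trend": ground_trend.rel_trend,
            "ground_rel_ci_lo": ground_trend.rel_ci[0],
            "ground_rel_ci_hi": ground_trend.rel_ci[1],
            "trend_difference": trend_difference(
                sat_trend.rel_trend, ground_trend.rel_trend
            ),
        })
    return pd.DataFrame(rows)


def trend_table(pwm_frame: pd.DataFrame, alpha: float = 0.01,
                subperiods: list[tuple[int, int]] | None = None) -> pd.DataFrame:
    """Per-region trend rows from a PWM table (columns region_id, year,
    pwm_ppb); sub-period rows use the full-period long-term mean."""
    rows = []
    for rid, gdf in pwm_frame.groupby("region_id"):
        gdf = gdf.sort_values("year")
        years = gdf["year"].to_numpy()
        vals = gdf["pwm_ppb"].to_numpy()
        est = ols_trend(years, vals)
        name = gdf["region_name"].iloc[0]
        rows.append(_trend_row(rid, name, "full", est, alpha))
        for (a, b) in subperiods or []:
            rows.append(_trend_row(rid, name, f"{a}-{b}",
                                   subperiod_trend(years, vals, a, b), alpha))
    return pd.DataFrame(rows)


def _trend_row(rid, name, period, est: TrendEstimate, alpha):
    return {
        "region_id": rid, "region_name": name, "period": period,
        "slope_ppb_yr": est.slope, "ci_lo": est.ci[0], "ci_hi": est.ci[1],
        "p": est.p, "mean_ppb": est.longterm_mean,
        "rel_trend_pct": est.rel_trend,
        "rel_ci_lo": est.rel_ci[0], "rel_ci_hi": est.rel_ci[1],
        "n_years": est.n, "significant": est.significant(alpha),
    }
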