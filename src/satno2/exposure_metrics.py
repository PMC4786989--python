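"""Population-weighted regional exposure statistics.

PWM (population-weighted mean) = sum(pop_i * C_i) / sum(pop_i) over a
region's unmasked cells; weighted percentiles and CDFs in cumulative-
population space; percent-change reporting arithmetic; and head counts
of people living under statistically significant trends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_world import PopulationSeries, RegionMask

__all__ = [
    "PwmSeries",
    "WeightedCdf",
    "interpolate_population",
    "pwm",
    "pw_percentile",
    "pw_cdf",
    "percent_change",
    "population_under_trend",
    "pwm_table",
]


@dataclass
class PwmSeries:
    region_id: int
    years: list[int]
    pwm: np.ndarray         # [ppb]
    population: np.ndarray  # persons actually weighted each year


@dataclass
class WeightedCdf:
    """Sorted concentrations with cumulative population fraction."""

    region_id: int
    year: int
    concentration: np.ndarray
    cum_fraction: np.ndarray


def interpolate_population(series: PopulationSeries, year: int) -> np.ndarray:
    """Cellwise linear interpolation between 5-year snapshots.

    Years outside the snapshot range clamp to the nearest snapshot.
    """
    ys = series.years
    if year <= ys[0]:
        return series.counts[ys[0]].copy()
    if year >= ys[-1]:
        return series.counts[ys[-1]].copy()
    hi = min(y for y in ys if y >= year)
    lo = max(y for y in ys if y <= year)
    if hi == lo:
        return series.counts[lo].copy()
    t = (year - lo) / (hi - lo)
    return (1 - t) * series.counts[lo] + t * series.counts[hi]


def _region_arrays(field, population, region_mask, region_id):
    sel = region_mask.cells(region_id) if region_id is not None else np.ones_like(field, bool)
    sel = sel & ~np.isnan(field)
    c = field[sel]
    p = population[sel]
    if c.size == 0 or p.sum() <= 0:
        raise ValueError(f"region {region_id}: no populated unmasked cells")
    return c, p


def pwm(field: np.ndarray, population: np.ndarray, region_mask: RegionMask | None = None,
        region_id: int | None = None) -> float:
    """Population-weighted mean concentration over a region.

    Masked cells drop out of both sums (weight renormalization).
    """
    c, p = _region_arrays(field, population, region_mask, region_id)
    return float(np.sum(p * c) / np.sum(p))


def _sorted_cum(field, population, region_mask, region_id):
    c, p = _region_arrays(field, population, region_mask, region_id)
    order = np.argsort(c, kind="stable")
    c, p = c[order], p[order]
    cum = np.cumsum(p) / p.sum()
    return c, cum


def pw_percentile(field: np.ndarray, population: np.ndarray,
                  region_mask: RegionMask | None, region_id: int | None,
                  q: float) -> float:
    """Weighted empirical quantile of the exposure distribution.

    Cells are sorted by concentration; the percentile is the
    concentration where the cumulative population fraction first
    reaches q/100, linearly interpolated between adjacent cells in
    cumulative-population space.
    """
    if not 0 < q < 100:
        raise ValueError("q must lie in (0, 100)")
    c, cum = _sorted_cum(field, population, region_mask, region_id)
    return float(np.interp(q / 100.0, cum, c, left=c[0], right=c[-1]))


def pw_cdf(field: np.ndarray, population: np.ndarray,
           region_mask: RegionMask | None, region_id: int | None,
           year: int = 0) -> WeightedCdf:
    """Cumulative population fraction vs concentration (fraction 0 at the
    minimum, 1 at the maximum)."""
    c, cum = _sorted_cum(field, population, region_mask, region_id)
    conc = np.concatenate([[c[0]], c])
    frac = np.concatenate([[0.0], cum])
    return WeightedCdf(region_id if region_id is not None else 0, year, conc, frac)


def percent_change(v_start: float, v_end: float) -> tuple[int, float]:
    """Signed percent change, rounded half away from zero for reporting.

    Returns ``(rounded, exact)``; e.g. 15.9 -> 13.4 ppb gives (-16,
    -15.72...).  The unrounded value is always preserved alongside.
    """
    if v_start <= 0:
        raise ValueError("percent change undefined for nonpositive start value")
    exact = 100.0 * (v_end - v_start) / v_start
    rounded = int(np.floor(abs(exact) + 0.5) * np.sign(exact))
    return rounded, exact


def population_under_trend(trend_table: pd.DataFrame, population: np.ndarray,
                           region_mask: RegionMask, alpha: float = 0.01
                           ) -> tuple[float, float]:
    """Persons in regions with significant increasing / decreasing trends.

    ``trend_table`` needs columns ``region_id``, ``slope`` and ``p``;
    significance is p <= alpha.  Returns ``(pop_increasing,
    pop_decreasing)``.
    """
    up = down = 0.0
    for _, row in trend_table.iterrows():
        if row["p"] <= alpha:
            tot = float(population[region_mask.cells(int(row["region_id"]))].sum())
            if row["slope"] > 0:
                up += tot
            elif row["slope"] < 0:
                down += tot
    return up, down


def pwm_table(surface_years: list[int], surface_fields: np.ndarray,
              pop_series: PopulationSeries, region_mask: RegionMask,
              include_global: bool = True) -> pd.DataFrame:
    """Per-region, per-year PWM rows (region id 0 = all regions pooled)."""
    rows = []
    rids = region_mask.region_ids() + ([0] if include_global else [])
    for k, year in enumerate(surface_years):
        popy = interpolate_population(pop_series, year)
        for rid in rids:
            sel_id = None if rid == 0 else rid
            try:
                value = pwm(surface_fields[k], popy, region_mask, sel_id)
            except ValueError:
                value = np.nan
            sel = np.ones(popy.shape, bool) if rid == 0 else region_mask.cells(rid)
            sel = sel & ~np.isnan(surface_fields[k])
            rows.append({
                "region_id": rid,
                "region_name": "global" if rid == 0 else region_mask.names[rid],
                "year": year,
                "pwm_ppb": value,
                "population": float(popy[sel].sum()),
            })
    return pd.DataFrame(rows)
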