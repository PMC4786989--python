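"""Quality control and regridding of sensor granules.

Turns raw footprint observations into daily 0.1-degree column fields:
cloud and snow filtering, averaging-kernel a-priori replacement, and
overlap-area-weighted regridding (spatial oversampling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import footprint_means, overlap_matrices, rect_area_weights
from .grid import GridSpec
from .synthetic_world import (
    DailyGranule,
    SensorSpec,
    footprint_layout,
    sensor_offset_counts,
)

__all__ = [
    "DailyColumnField",
    "SnowFreeWindow",
    "apply_cloud_filter",
    "apply_averaging_kernel_correction",
    "correct_granule",
    "regrid_granule",
    "snow_free_window",
    "apply_snow_filter",
    "accumulate_annual",
]

log = logging.getLogger(__name__)


@dataclass
class DailyColumnField:
    """One sensor-day on the analysis grid.

    ``values`` holds the overlap-area-weighted mean column per cell
    (NaN where no footprint touched the cell); ``weight`` the summed
    overlap area (cos-lat weighted degrees^2).  Negative columns from
    retrieval noise are retained — clipping them would bias low-signal
    means; only final annual surface means are floored at zero.
    """

    year: int
    doy: int
    sensor: str
    grid: GridSpec
    values: np.ndarray
    weight: np.ndarray

    @property
    def mask(self) -> np.ndarray:
        return self.weight <= 0


# ----------------------------------------------------------------------
# cloud filter
# ----------------------------------------------------------------------
def apply_cloud_filter(granule: DailyGranule, max_cloud: float = 0.5) -> DailyGranule:
    """Drop bright footprints with cloud radiance fraction strictly > 0.5.

    Footprints with a missing (NaN) fraction are also dropped and
    counted separately.
    """
    cf = granule.cloud_frac
    missing = np.isnan(cf)
    keep = ~missing & (cf <= max_cloud)
    n_cloud = int((~keep & ~missing).sum())
    n_missing = int(missing.sum())
    if n_cloud or n_missing:
        log.debug(
            "cloud filter %s %d/%03d: removed %d bright, %d missing-fraction",
            granule.sensor, granule.year, granule.doy, n_cloud, n_missing,
        )
    return granule.subset(keep)


# ----------------------------------------------------------------------
# averaging-kernel correction
# ----------------------------------------------------------------------
def apply_averaging_kernel_correction(column, kernel, model_profile):
    """Replace the retrieval a priori with the model profile.

    corrected = column * sum_l(x_l) / sum_l(A_l x_l), with x the model
    partial-column profile and A the averaging kernel.  A unit kernel is
    the identity; the factor is invariant to rescaling x.  Observations
    with sum(A x) <= 0 are flagged invalid (NaN).

    Accepts scalars (one observation) or stacked arrays: ``column``
    (F,), ``kernel`` and ``model_profile`` (F, L).
    """
    column = np.asarray(column, dtype=float)
    kernel = np.atleast_2d(np.asarray(kernel, dtype=float))
    x = np.atleast_2d(np.asarray(model_profile, dtype=float))
    if kernel.shape != x.shape:
        raise ValueError("kernel and model profile must have equal layer counts")
    denom = np.sum(kernel * x, axis=-1)
    num = np.sum(x, axis=-1)
    factor = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    out = column * np.squeeze(factor)
    if np.ndim(column) == 0:
        return float(out)
    return out


def correct_granule(granule: DailyGranule) -> DailyGranule:
    """Kernel-correct all footprints; invalid ones are dropped."""
    corrected = apply_averaging_kernel_correction(
        granule.column, granule.kernel, granule.apriori
    )
    corrected = np.atleast_1d(corrected)
    g = granule.subset(np.ones(len(granule), dtype=bool))
    g.column = corrected
    ok = ~np.isnan(corrected)
    if not ok.all():
        log.debug("kernel correction flagged %d footprints invalid", int((~ok).sum()))
        g = g.subset(ok)
    return g


# ----------------------------------------------------------------------
# snow filter
# ----------------------------------------------------------------------
@dataclass
class SnowFreeWindow:
    """Per-cell day-of-year interval [start, end] (inclusive), common to
    all years: the intersection of each year's longest snow-free run —
    the 'shortest snow-free season'.  Cells snow-covered in any year get
    an empty window (start > end)."""

    start: np.ndarray
    end: np.ndarray

    def allows(self, doy: int) -> np.ndarray:
        return (self.start <= doy) & (doy <= self.end)

    @property
    def empty(self) -> np.ndarray:
        return self.start > self.end


def _longest_free_run(snow: np.ndarray, doys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Longest consecutive snow-free run per cell for one year.

    ``snow`` is (ndays, ...) boolean.  Returns (start_doy, end_doy); a
    cell with snow every sampled day gets (367, 0) == empty.
    """
    shape = snow.shape[1:]
    run_len = np.zeros(shape, dtype=int)
    run_start = np.zeros(shape, dtype=int)
    best_len = np.zeros(shape, dtype=int)
    best_start = np.full(shape, 367, dtype=int)
    best_end = np.zeros(shape, dtype=int)
    for di, doy in enumerate(doys):
        free = ~snow[di]
        starting = free & (run_len == 0)
        run_start[starting] = doy
        run_len[free] += 1
        run_len[~free] = 0
        better = free & (run_len > best_len)
        best_len[better] = run_len[better]
        best_start[better] = run_start[better]
        best_end[better] = doy
    return best_start, best_end


def snow_free_window(
    snow_daily_flags: dict[int, np.ndarray] | np.ndarray,
    doys: np.ndarray,
    mode: str = "intersection",
):
    """Derive per-cell snow-free windows from daily snow flags.

    ``snow_daily_flags`` maps year -> (ndays, ...) boolean snow presence
    (or a single (nyears, ndays, ...) array).  Each year contributes its
    longest snow-free run; ``mode="intersection"`` (default) intersects
    runs over years into one window applied identically to all years,
    guaranteeing identical seasonal sampling across sensor eras;
    ``mode="per-year"`` returns one window per year.
    """
    if isinstance(snow_daily_flags, np.ndarray):
        per_year = {i: snow_daily_flags[i] for i in range(snow_daily_flags.shape[0])}
    else:
        per_year = snow_daily_flags
    windows = {y: _longest_free_run(f, doys) for y, f in per_year.items()}
    if mode == "per-year":
        return {y: SnowFreeWindow(s, e) for y, (s, e) in windows.items()}
    if mode != "intersection":
        raise ValueError("mode must be 'intersection' or 'per-year'")
    starts = np.stack([s for s, _ in windows.values()])
    ends = np.stack([e for _, e in windows.values()])
    start, end = starts.max(axis=0), ends.min(axis=0)
    n_empty = int((start > end).sum())
    if n_empty:
        log.debug("snow window: %d cells have no common snow-free season", n_empty)
    return SnowFreeWindow(start, end)


def apply_snow_filter(obj, window: SnowFreeWindow, grid: GridSpec | None = None):
    """Remove observations outside the snow-free window.

    For a :class:`DailyColumnField`, cells whose window excludes the
    field's day are masked.  For a granule, footprints whose centre cell
    excludes the day are dropped (``grid`` required to locate centres).
    """
    if isinstance(obj, DailyColumnField):
        allowed = window.allows(obj.doy)
        out = DailyColumnField(
            obj.year, obj.doy, obj.sensor, obj.grid,
            obj.values.copy(), obj.weight.copy(),
        )
        out.values[~allowed] = np.nan
        out.weight[~allowed] = 0.0
        return out
    granule: DailyGranule = obj
    if grid is None:
        raise ValueError("grid required to snow-filter a granule")
    ci = np.clip(((0.5 * (granule.lat_lo + granule.lat_hi) - grid.lat0) / grid.dlat
                  ).astype(int), 0, grid.nlat - 1)
    cj = np.clip(((0.5 * (granule.lon_lo + granule.lon_hi) - grid.lon0) / grid.dlon
                  ).astype(int), 0, grid.nlon - 1)
    keep = window.allows(granule.doy)[ci, cj]
    return granule.subset(keep)


# ----------------------------------------------------------------------
# regridding
# ----------------------------------------------------------------------
def regrid_granule(
    granule: DailyGranule, grid: GridSpec, min_overlap_frac: float = 0.01
) -> DailyColumnField:
    """Overlap-area-weighted regridding of footprints to the fine grid.

    Each cell receives the mean of all covering footprints weighted by
    the overlap area (cos-lat planar rectangles); the summed overlap
    area is kept as the observation weight.  Cells with no overlap are
    masked.  Repeating this day after day with shifting footprints is
    the spatial-oversampling mechanism that resolves sub-footprint
    structure in long-term means.
    """
    values = np.full(grid.shape, np.nan)
    weight = np.zeros(grid.shape)
    if len(granule):
        olat, olon = overlap_matrices(
            grid, granule.lon_lo, granule.lon_hi, granule.lat_lo, granule.lat_hi,
            min_frac=min_overlap_frac,
        )
        olatw = rect_area_weights(grid, olat)  # (F, nlat)
        weight = olatw.T @ olon  # (nlat, nlon)
        num = (olatw * granule.column[:, None]).T @ olon
        covered = weight > 0
        values[covered] = num[covered] / weight[covered]
    return DailyColumnField(granule.year, granule.doy, granule.sensor, grid, values, weight)


def sensor_smooth(field: np.ndarray, grid: GridSpec, sensor: SensorSpec,
                  min_overlap_frac: float = 0.01) -> np.ndarray:
    """Expected long-term smearing of a static field by a sensor.

    Applies the sensor's observation operator (footprint averaging plus
    overlap-weighted regridding) for every band phase and placement
    offset in its deterministic cycle, with equal weight.  The result is
    the exact long-term mean a noise- and cloud-free sensor would record
    of an unchanging field — the operator-consistent alternative to
    approximating a coarse sensor's smearing with a footprint-sized
    boxcar.  NaN cells are excluded from footprint averages.
    """
    num = np.zeros(grid.shape)
    wsum = np.zeros(grid.shape)
    nx, ny = sensor_offset_counts(grid, sensor)
    for phase in range(sensor.revisit):
        for ix in range(nx):
            for iy in range(ny):
                rects = footprint_layout(grid, sensor, phase,
                                         ix * grid.dlon, iy * grid.dlat)
                olat, olon = overlap_matrices(grid, rects[0], rects[1],
                                              rects[2], rects[3],
                                              min_frac=min_overlap_frac)
                col = footprint_means(grid, field, olat, olon, skip_nan=True)
                olatw = rect_area_weights(grid, olat)
                bad = np.isnan(col)
                if bad.any():
                    olatw[bad] = 0.0
                    col = np.where(bad, 0.0, col)
                num += (olatw * col[:, None]).T @ olon
                wsum += olatw.T @ olon
    out = np.full(grid.shape, np.nan)
    covered = wsum > 0
    out[covered] = num[covered] / wsum[covered]
    return out


# ----------------------------------------------------------------------
# temporal aggregation
# ----------------------------------------------------------------------
def accumulate_annual(daily_fields) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weight-averaged annual mean of daily column fields.

    Returns ``(mean, total_weight, ndays, valid)`` where ``valid`` is the
    (ndays, nlat, nlon) boolean retrieval-day mask, the input to the
    sampling-bias correction.  ``mean`` is NaN where no day had data.
    """
    fields = list(daily_fields)
    if not fields:
        raise ValueError("no daily fields to accumulate")
    grid = fields[0].grid
    num = np.zeros(grid.shape)
    wsum = np.zeros(grid.shape)
    ndays = np.zeros(grid.shape, dtype=int)
    valid = np.zeros((len(fields), *grid.shape), dtype=bool)
    for d, f in enumerate(fields):
        ok = f.weight > 0
        valid[d] = ok
        num[ok] += f.weight[ok] * f.values[ok]
        wsum[ok] += f.weight[ok]
        ndays[ok] += 1
    mean = np.full(grid.shape, np.nan)
    covered = wsum > 0
    mean[covered] = num[covered] / wsum[covered]
    return mean, wsum, ndays, valid
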