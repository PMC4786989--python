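"""Cross-sensor harmonization into a resolution-consistent annual record.

The fine-resolution reference sensor defines the record's effective
resolution.  Coarse-sensor years are ratio-downscaled: multiplied by the
ratio of the reference's temporally averaged fine field to its boxcar-
smoothed version, transferring fine spatial texture under the assumption
that relative spatial gradients persist.  The late sensor is scaled by
the per-cell long-term reference/target ratio over their overlap.
Continuity across sensor boundaries is diagnosed with per-pixel z-scores
of neighbouring-year differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import GridSpec

__all__ = [
    "RatioField",
    "HarmonizedRecord",
    "boxcar_smooth",
    "ratio_downscale",
    "crosscal_scale",
    "build_harmonized_record",
    "overlap_correlation",
    "boundary_zscores",
]

log = logging.getLogger(__name__)


@dataclass
class RatioField:
    """Dimensionless downscaling ratios; 1 where the denominator fell
    below the floor."""

    values: np.ndarray
    reference_period: tuple[int, int]
    floor: float


@dataclass
class HarmonizedRecord:
    """Annual mean columns at the reference sensor's effective resolution."""

    grid: GridSpec
    years: list[int]
    fields: np.ndarray  # (nyears, nlat, nlon)
    provenance: dict[int, tuple[str, str]]  # year -> (sensor, transform)

    def field(self, year: int) -> np.ndarray:
        return self.fields[self.years.index(year)]


def _window_cells(window_deg: float, cell_deg: float) -> int:
    if window_deg < cell_deg:
        raise ValueError("smoothing window smaller than one cell")
    n = int(np.ceil(window_deg / cell_deg - 1e-9))
    return n if n % 2 == 1 else n + 1


def _box_sum_1d(arr: np.ndarray, n: int, axis: int) -> np.ndarray:
    """Centered moving sum with window truncation at the edges."""
    half = n // 2
    arr = np.moveaxis(arr, axis, 0)
    c = np.concatenate([np.zeros((1, *arr.shape[1:])), np.cumsum(arr, axis=0)], axis=0)
    m = arr.shape[0]
    idx_hi = np.minimum(np.arange(m) + half + 1, m)
    idx_lo = np.maximum(np.arange(m) - half, 0)
    out = c[idx_hi] - c[idx_lo]
    return np.moveaxis(out, 0, axis)


def boxcar_smooth(values: np.ndarray, window_lon_deg: float, window_lat_deg: float,
                  grid: GridSpec | None = None, cell: float = 0.1) -> np.ndarray:
    """Two-dimensional boxcar (unweighted moving mean) smoothing.

    The window is given in degrees and converted to an odd cell count;
    it is truncated at grid edges, and masked (NaN) cells are excluded
    from each window mean.  Mimics the horizontal smearing of a coarse
    footprint (e.g. 3.2 x 0.4 degrees for a 320 km x 40 km pixel).
    """
    dlat = grid.dlat if grid is not None else cell
    dlon = grid.dlon if grid is not None else cell
    if values.ndim == 1:
        n = _window_cells(window_lon_deg, dlon)
        ok = ~np.isnan(values)
        s = _box_sum_1d(np.where(ok, values, 0.0), n, 0)
        c = _box_sum_1d(ok.astype(float), n, 0)
        return np.where(c > 0, s / np.where(c > 0, c, 1.0), np.nan)
    nlon = _window_cells(window_lon_deg, dlon)
    nlat = _window_cells(window_lat_deg, dlat)
    ok = ~np.isnan(values)
    s = _box_sum_1d(_box_sum_1d(np.where(ok, values, 0.0), nlat, 0), nlon, 1)
    c = _box_sum_1d(_box_sum_1d(ok.astype(float), nlat, 0), nlon, 1)
    return np.where(c > 0, s / np.where(c > 0, c, 1.0), np.nan)


def make_ratio(fine_reference_mean: np.ndarray, smoothed_reference_mean: np.ndarray,
               floor: float | None = None, floor_frac: float = 0.05,
               reference_period: tuple[int, int] = (0, 0)) -> RatioField:
    """Fine/smoothed reference ratio with a near-zero-denominator floor.

    Below the floor (default 5% of the global-mean smoothed reference)
    the ratio is set to 1: no texture is transferred where the reference
    signal is too weak to define one.
    """
    if floor is None:
        floor = floor_frac * float(np.nanmean(smoothed_reference_mean))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = fine_reference_mean / smoothed_reference_mean
    weak = ~(smoothed_reference_mean >= floor)
    ratio = np.where(weak, 1.0, ratio)
    return RatioField(ratio, reference_period, float(floor))


def ratio_downscale(coarse_annual: np.ndarray, fine_reference_mean: np.ndarray,
                    smoothed_reference_mean: np.ndarray,
                    floor: float | None = None) -> np.ndarray:
    """Transfer fine reference texture onto a coarse-sensor annual mean."""
    if coarse_annual.shape != fine_reference_mean.shape or \
            coarse_annual.shape != smoothed_reference_mean.shape:
        raise ValueError("fields must share one grid")
    ratio = make_ratio(fine_reference_mean, smoothed_reference_mean, floor)
    return coarse_annual * ratio.values


def crosscal_scale(target_annual: np.ndarray, reference_longterm_mean: np.ndarray,
                   target_longterm_mean: np.ndarray, floor: float | None = None,
                   clip: tuple[float, float] = (0.1, 10.0)) -> np.ndarray:
    """Scale a late-era sensor by the long-term reference/target ratio.

    A uniform multiplicative inter-sensor bias cancels exactly; the
    per-cell ratio is clipped to ``clip`` to contain noisy low-signal
    cells (clipping logged).
    """
    if floor is None:
        floor = 0.05 * float(np.nanmean(target_longterm_mean))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = reference_longterm_mean / target_longterm_mean
    ratio = np.where(~(target_longterm_mean >= floor), 1.0, ratio)
    n_clip = int(np.nansum((ratio < clip[0]) | (ratio > clip[1])))
    if n_clip:
        log.debug("crosscal: clipped %d cells to %s", n_clip, clip)
    ratio = np.clip(ratio, clip[0], clip[1])
    return target_annual * ratio


def build_harmonized_record(
    annuals_by_sensor: dict[str, dict[int, np.ndarray]],
    grid: GridSpec,
    reference_sensor: str = "sciamachy",
    era_assignment: dict[str, tuple[int, int]] | None = None,
    ref_downscale: tuple[int, int] = (2003, 2005),
    ref_crosscal: tuple[int, int] = (2007, 2011),
    years: tuple[int, int] = (1996, 2012),
    boxcar_window: tuple[float, float] = (3.2, 0.4),
    floor_frac: float = 0.05,
    smoothed_reference: np.ndarray | None = None,
) -> HarmonizedRecord:
    """Assemble the multi-sensor record at the reference resolution.

    Whole years are assigned to single sensors (``era_assignment``, by
    default the coarse sensor through 2003, the reference 2004-2011 and
    the late sensor in 2012).  Coarse-era years pass through
    :func:`ratio_downscale` against the reference's ``ref_downscale``
    mean; late-era years through :func:`crosscal_scale` over the
    ``ref_crosscal`` overlap; reference years pass through unchanged.
    Annual means are floored at zero on output.

    ``smoothed_reference`` overrides the boxcar-smoothed reference mean
    in the downscaling ratio, e.g. with the coarse sensor's own
    observation operator applied to the reference field.
    """
    if era_assignment is None:
        era_assignment = {"gome": (1996, 2003), "sciamachy": (2004, 2011),
                          "gome2": (2012, 2012)}
    ref_annuals = annuals_by_sensor[reference_sensor]
    for y in range(ref_downscale[0], ref_downscale[1] + 1):
        if y not in ref_annuals:
            raise ValueError(f"reference sensor missing downscale-period year {y}")

    fine_ref = _nanmean_stack([ref_annuals[y] for y in
                               range(ref_downscale[0], ref_downscale[1] + 1)])
    if smoothed_reference is not None:
        smoothed_ref = smoothed_reference
    else:
        smoothed_ref = boxcar_smooth(fine_ref, boxcar_window[0], boxcar_window[1],
                                     grid=grid)
    floor = floor_frac * float(np.nanmean(smoothed_ref))

    year_list = list(range(years[0], years[1] + 1))
    fields = np.full((len(year_list), *grid.shape), np.nan)
    provenance: dict[int, tuple[str, str]] = {}
    crosscal_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    for k, year in enumerate(year_list):
        sensor = next(
            (s for s, (a, b) in era_assignment.items() if a <= year <= b and
             s in annuals_by_sensor), None)
        if sensor is None or year not in annuals_by_sensor[sensor]:
            raise ValueError(f"year {year} covered by no sensor in the assignment")
        annual = annuals_by_sensor[sensor][year]
        if sensor == reference_sensor:
            fields[k] = annual
            provenance[year] = (sensor, "native")
        elif year < era_assignment[reference_sensor][0]:
            fields[k] = ratio_downscale(annual, fine_ref, smoothed_ref, floor)
            provenance[year] = (sensor, "ratio_downscale")
        else:
            if sensor not in crosscal_cache:
                w = range(ref_crosscal[0], ref_crosscal[1] + 1)
                missing = [y for y in w if y not in ref_annuals or
                           y not in annuals_by_sensor[sensor]]
                if len(missing) == len(list(w)):
                    raise ValueError("empty cross-calibration overlap window")
                have = [y for y in w if y not in missing]
                crosscal_cache[sensor] = (
                    _nanmean_stack([ref_annuals[y] for y in have]),
                    _nanmean_stack([annuals_by_sensor[sensor][y] for y in have]),
                )
            ref_lt, tgt_lt = crosscal_cache[sensor]
            fields[k] = crosscal_scale(annual, ref_lt, tgt_lt)
            provenance[year] = (sensor, "crosscal_scale")
    fields = np.where(np.isnan(fields), np.nan, np.maximum(fields, 0.0))
    return HarmonizedRecord(grid, year_list, fields, provenance)


def _nanmean_stack(fields: list[np.ndarray]) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        out = np.nanmean(np.stack(fields), axis=0)
    return out


def overlap_correlation(field_a: np.ndarray, field_b: np.ndarray,
                        mask: np.ndarray | None = None) -> float:
    """Pearson r over jointly unmasked cells (>= 3 required)."""
    ok = ~np.isnan(field_a) & ~np.isnan(field_b)
    if mask is not None:
        ok &= mask
    if ok.sum() < 3:
        raise ValueError("fewer than 3 jointly unmasked cells")
    a, b = field_a[ok], field_b[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a constant field")
    return float(np.corrcoef(a, b)[0, 1])


def boundary_zscores(pixel_annual_series: np.ndarray, boundary_indices,
                     threshold: float = 1.5) -> tuple[np.ndarray, float]:
    """z-scores of sensor-boundary year-to-year differences.

    ``pixel_annual_series`` is (nyears, npixels) (or (nyears,) for one
    pixel); ``boundary_indices`` lists the indices of the difference
    pairs to score (difference ``d_t = v[t+1] - v[t]`` has index ``t``).
    For each pixel the z of a boundary pair is
    ``(d_boundary - mean(d)) / sd(d)`` with the sample sd over all
    consecutive pairs; a constant-difference series has sd 0 and z
    defined as 0.  Returns ``(|z| with shape (nboundaries, npixels),
    fraction of pixel-boundary cases with |z| <= threshold)``.
    """
    series = np.asarray(pixel_annual_series, dtype=float)
    one_d = series.ndim == 1
    if one_d:
        series = series[:, None]
    if series.shape[0] < 4:
        raise ValueError("need at least 4 years for boundary z-scores")
    d = np.diff(series, axis=0)
    mu = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    bi = np.atleast_1d(np.asarray(boundary_indices, dtype=int))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (d[bi] - mu[None, :]) / sd[None, :]
    z = np.where(sd[None, :] == 0, 0.0, z)
    absz = np.abs(z)
    frac = float(np.mean(absz <= threshold))
    return (absz[:, 0] if one_d else absz), frac
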