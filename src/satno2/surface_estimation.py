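"""Column-to-surface conversion and sampling-bias correction.

Ground-level NO2 is estimated by scaling the column density with the
model surface-to-column ratio, resampled to the analysis grid by block
(nearest-neighbour) assignment so fine spatial texture comes from the
satellite, not the model.  Annual means are corrected for nonrandom
sampling with a per-cell factor: the model surface mean over all days
divided by its mean over successful-retrieval days, compensating the
seasonal/cloud-driven loss of (typically high-NO2 winter) days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec
from .synthetic_world import block_repeat

__all__ = [
    "SurfaceRecord",
    "resample_to_fine",
    "column_to_surface",
    "sampling_correction_factor",
    "annual_surface_mean",
    "build_surface_record",
]


@dataclass
class SurfaceRecord:
    """Per-year annual mean surface NO2 [ppb] with correction metadata."""

    grid: GridSpec
    years: list[int]
    surface: np.ndarray   # (nyears, nlat, nlon), NaN where masked
    factors: np.ndarray   # sampling-correction factor applied (NaN if masked)
    ndays: np.ndarray     # valid retrieval days per cell-year

    def field(self, year: int) -> np.ndarray:
        return self.surface[self.years.index(year)]


def resample_to_fine(coarse_values: np.ndarray, coarse_grid: GridSpec,
                     fine_grid: GridSpec) -> np.ndarray:
    """Nearest-neighbour (block) resampling from model to analysis grid."""
    flat = int(round(coarse_grid.dlat / fine_grid.dlat))
    flon = int(round(coarse_grid.dlon / fine_grid.dlon))
    out = block_repeat(coarse_values, flat, flon)
    if out.shape != fine_grid.shape:
        raise ValueError("grids are not nested; cannot block-resample")
    return out


def column_to_surface(column_field: np.ndarray, ctm_ratio_field: np.ndarray) -> np.ndarray:
    """surface [ppb] = column [1e15 molec cm^-2] x ratio [ppb per 1e15].

    Masks (NaN) propagate; a negative ratio violates the surrogate
    construction and raises.
    """
    if np.any(ctm_ratio_field < 0):
        raise ValueError("negative surface-to-column ratio")
    return column_field * ctm_ratio_field


def sampling_correction_factor(ctm_surface_daily: np.ndarray,
                               retrieval_day_mask: np.ndarray) -> np.ndarray:
    """Per-cell annual correction for incomplete temporal sampling.

    factor = mean(model surface over ALL days) /
             mean(model surface over retrieval days);
    1 when every day was retrieved, NaN (cell-year masked) when none was.
    Both inputs are (ndays, ...) with the mask boolean.
    """
    if ctm_surface_daily.shape != retrieval_day_mask.shape:
        raise ValueError("daily surface and retrieval mask shapes differ")
    all_mean = ctm_surface_daily.mean(axis=0)
    n_ret = retrieval_day_mask.sum(axis=0)
    ret_sum = np.where(retrieval_day_mask, ctm_surface_daily, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ret_mean = ret_sum / n_ret
        factor = all_mean / ret_mean
    return np.where(n_ret > 0, factor, np.nan)


def sampling_correction_factor_weighted(ctm_surface_daily: np.ndarray,
                                        day_weights: np.ndarray) -> np.ndarray:
    """Sampling correction against observation-weighted day sampling.

    Generalises :func:`sampling_correction_factor` to continuous day
    weights: when a cell's annual mean weights days by observation
    weight (summed footprint overlap), days that lost part of their
    footprints to QC are down-weighted rather than merely missing, so
    the correction must compare the all-day model mean with the model
    mean under the same weights.  With binary weights this reduces to
    the mask-based factor.
    """
    if ctm_surface_daily.shape != day_weights.shape:
        raise ValueError("daily surface and weight shapes differ")
    all_mean = ctm_surface_daily.mean(axis=0)
    wsum = day_weights.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w_mean = (day_weights * ctm_surface_daily).sum(axis=0) / wsum
        factor = all_mean / w_mean
    return np.where(wsum > 0, factor, np.nan)


def annual_surface_mean(daily_surface_fields: np.ndarray, weights: np.ndarray,
                        factors: np.ndarray | float = 1.0,
                        min_days: int = 5) -> np.ndarray:
    """Weighted annual mean of daily values, sampling-corrected.

    ``daily_surface_fields`` and ``weights`` are (ndays, ...); days with
    zero weight (or NaN value) do not contribute.  Cells with fewer than
    ``min_days`` contributing days are masked (the minimum echoes the
    five-coincident-observations station rule).  Output is floored at 0.
    """
    if min_days < 1:
        raise ValueError("min_days must be >= 1")
    ok = (weights > 0) & ~np.isnan(daily_surface_fields)
    w = np.where(ok, weights, 0.0)
    v = np.where(ok, daily_surface_fields, 0.0)
    wsum = w.sum(axis=0)
    ndays = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (w * v).sum(axis=0) / wsum
    mean = mean * np.asarray(factors, dtype=float)
    mean = np.where(ndays >= min_days, mean, np.nan)
    return np.maximum(mean, 0.0, where=~np.isnan(mean), out=mean)


def build_surface_record(record_years: list[int], column_fields: np.ndarray,
                         fine_ratio: np.ndarray, grid: GridSpec,
                         factors: np.ndarray | None = None,
                         ndays: np.ndarray | None = None,
                         min_days: int = 5) -> SurfaceRecord:
    """Convert a harmonized annual column record to a surface record.

    ``column_fields`` is (nyears, nlat, nlon); ``factors`` the per-year
    sampling-correction fields (1 everywhere when the correction is off)
    and ``ndays`` the per-year valid-day counts used for the min-days
    mask.  Annual means are floored at zero.
    """
    n = len(record_years)
    if factors is None:
        factors = np.ones((n, *grid.shape))
    if ndays is None:
        ndays = np.full((n, *grid.shape), min_days, dtype=int)
    surface = np.empty_like(column_fields)
    for k in range(n):
        s = column_to_surface(column_fields[k], fine_ratio) * factors[k]
        s = np.where(ndays[k] >= min_days, s, np.nan)
        surface[k] = np.maximum(s, 0.0, where=~np.isnan(s), out=s)
    return SurfaceRecord(grid, list(record_years), surface, np.asarray(factors),
                         np.asarray(ndays))
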