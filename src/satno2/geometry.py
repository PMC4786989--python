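"""Footprint-rectangle / grid-cell overlap geometry.

A sensor footprint is a latitude/longitude-aligned rectangle in degrees.
Its overlap with every cell of a regular grid factorises into a
longitude part and a latitude part, so one footprint's overlap pattern
is the outer product of two short vectors.  Keeping the two factors
separate makes both regridding (scatter of footprints onto cells) and
footprint averaging (gather of cells into footprints) a pair of small
matrix products.

Areas are planar rectangles weighted by cos(latitude) of the cell row,
adequate at the 0.1-degree scale of the analysis grid.
"""

from __future__ import annotations

import numpy as np

from .grid import GridSpec

__all__ = ["overlap_matrices", "footprint_means", "rect_area_weights"]


def overlap_matrices(
    grid: GridSpec,
    lon_lo: np.ndarray,
    lon_hi: np.ndarray,
    lat_lo: np.ndarray,
    lat_hi: np.ndarray,
    min_frac: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis overlap lengths between footprints and grid cells.

    Returns ``(olat, olon)`` with shapes ``(F, nlat)`` and ``(F, nlon)``,
    in degrees.  Overlaps smaller than ``min_frac`` of the cell extent on
    that axis are zeroed (numerical-noise control for slivers).
    """
    lon_lo = np.atleast_1d(np.asarray(lon_lo, dtype=float))
    lon_hi = np.atleast_1d(np.asarray(lon_hi, dtype=float))
    lat_lo = np.atleast_1d(np.asarray(lat_lo, dtype=float))
    lat_hi = np.atleast_1d(np.asarray(lat_hi, dtype=float))

    le = grid.lon_edges
    olon = np.minimum(lon_hi[:, None], le[None, 1:]) - np.maximum(
        lon_lo[:, None], le[None, :-1]
    )
    np.clip(olon, 0.0, None, out=olon)
    olon[olon < min_frac * grid.dlon] = 0.0

    te = grid.lat_edges
    olat = np.minimum(lat_hi[:, None], te[None, 1:]) - np.maximum(
        lat_lo[:, None], te[None, :-1]
    )
    np.clip(olat, 0.0, None, out=olat)
    olat[olat < min_frac * grid.dlat] = 0.0
    return olat, olon


def rect_area_weights(grid: GridSpec, olat: np.ndarray) -> np.ndarray:
    """Latitude overlap weighted by cos(lat) of each row: (F, nlat)."""
    return olat * grid.coslat[None, :]


def footprint_means(
    grid: GridSpec,
    field: np.ndarray,
    olat: np.ndarray,
    olon: np.ndarray,
    skip_nan: bool = False,
) -> np.ndarray:
    """Area-weighted mean of ``field`` over each footprint rectangle.

    ``field`` is (nlat, nlon); returns (F,).  NaNs in ``field`` propagate
    unless ``skip_nan`` is set, in which case masked cells are excluded
    from both numerator and the area normalisation.
    """
    olatw = rect_area_weights(grid, olat)
    if skip_nan:
        ok = ~np.isnan(field)
        num = np.einsum("fi,ij,fj->f", olatw, np.where(ok, field, 0.0), olon,
                        optimize=True)
        den = np.einsum("fi,ij,fj->f", olatw, ok.astype(float), olon, optimize=True)
    else:
        num = np.einsum("fi,ij,fj->f", olatw, field, olon, optimize=True)
        den = olatw.sum(axis=1) * olon.sum(axis=1)
    out = np.full(num.shape, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out
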