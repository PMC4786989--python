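"""Regular latitude-longitude grids and gridded scalar fields.

Everything in the pipeline is exchanged on a regular lat/lon raster
(0.1 degrees by default, mirroring the analysis grid of multi-sensor
NO2 column records).  Cells are half-open ``[lo, hi)`` intervals on both
axes with centres at ``origin + (index + 0.5) * cellsize``.  Missing
data are carried as NaN; a cell's relative area is ``dlat * dlon *
cos(lat_centre)``, the planar-rectangle approximation adequate at the
0.1-degree scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "GridField"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lat/lon raster.

    Parameters
    ----------
    lat0, lon0
        Southern / western edge of the grid, in degrees.
    nlat, nlon
        Number of rows (latitude) and columns (longitude).
    dlat, dlon
        Cell size in degrees; 0.1 x 0.1 by default.
    """

    lat0: float
    lon0: float
    nlat: int
    nlon: int
    dlat: float = 0.1
    dlon: float = 0.1

    def __post_init__(self) -> None:
        if self.nlat < 1 or self.nlon < 1:
            raise ValueError("grid must have at least one cell per axis")
        if self.dlat <= 0 or self.dlon <= 0:
            raise ValueError("cell size must be positive")

    # -- coordinates -------------------------------------------------
    @property
    def lat_edges(self) -> np.ndarray:
        return self.lat0 + self.dlat * np.arange(self.nlat + 1)

    @property
    def lon_edges(self) -> np.ndarray:
        return self.lon0 + self.dlon * np.arange(self.nlon + 1)

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat0 + self.dlat * (np.arange(self.nlat) + 0.5)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon0 + self.dlon * (np.arange(self.nlon) + 0.5)

    @property
    def lat1(self) -> float:
        """Northern edge."""
        return self.lat0 + self.dlat * self.nlat

    @property
    def lon1(self) -> float:
        """Eastern edge."""
        return self.lon0 + self.dlon * self.nlon

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def coslat(self) -> np.ndarray:
        """cos(latitude) at cell centres — the per-row area weight."""
        return np.cos(np.deg2rad(self.lat_centers))

    @property
    def cell_area(self) -> np.ndarray:
        """Relative cell area per row (degrees^2, cos-weighted)."""
        return self.dlat * self.dlon * self.coslat

    # -- lookup ------------------------------------------------------
    def locate(self, lat: float, lon: float) -> tuple[int, int]:
        """Return the (row, col) of the cell containing a point.

        Points on the northern/eastern outer edge are clamped inward so
        that stations sitting exactly on the boundary remain usable.
        """
        i = int(np.floor((lat - self.lat0) / self.dlat))
        j = int(np.floor((lon - self.lon0) / self.dlon))
        if not (0 <= i <= self.nlat and 0 <= j <= self.nlon):
            raise ValueError(f"point ({lat}, {lon}) outside grid extent")
        return min(i, self.nlat - 1), min(j, self.nlon - 1)

    def contains_rect(self, lon_lo, lon_hi, lat_lo, lat_hi) -> bool:
        eps = 1e-9
        return (
            lon_lo >= self.lon0 - eps
            and lon_hi <= self.lon1 + eps
            and lat_lo >= self.lat0 - eps
            and lat_hi <= self.lat1 + eps
        )


@dataclass
class GridField:
    """One scalar per grid cell, with NaN marking missing data."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """True where the cell has no valid value."""
        return np.isnan(self.values)

    def copy(self) -> "GridField":
        return GridField(self.grid, self.values.copy())

    def area_mean(self) -> float:
        """cos(lat)-weighted mean over valid cells."""
        w = np.broadcast_to(self.grid.cell_area[:, None], self.values.shape)
        ok = ~self.mask
        if not ok.any():
            return float("nan")
        return float(np.sum(self.values[ok] * w[ok]) / np.sum(w[ok]))
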