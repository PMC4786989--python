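"""NetCDF and CSV round-tripping.

Gridded fields travel as CF-style NetCDF (lat/lon centre coordinates,
NaN + ``missing_value`` marking masked cells) via xarray's scipy
backend; tabular outputs are plain CSV with a header row so runs can be
diffed textually.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec

__all__ = ["grid_to_dataset", "write_grid", "read_grid", "write_table", "read_table"]

_ENGINE = "scipy"


def grid_to_dataset(grid: GridSpec, variables: dict[str, tuple[tuple[str, ...], np.ndarray]],
                    extra_coords: dict | None = None, attrs: dict | None = None) -> xr.Dataset:
    """Pack (dims, array) variables into a dataset on the grid's coords."""
    coords = {"lat": grid.lat_centers, "lon": grid.lon_centers}
    if extra_coords:
        coords.update(extra_coords)
    ds = xr.Dataset({k: (dims, arr) for k, (dims, arr) in variables.items()}, coords=coords)
    ds.attrs.update(attrs or {})
    ds.attrs.setdefault("dlat", grid.dlat)
    ds.attrs.setdefault("dlon", grid.dlon)
    for v in ds.data_vars.values():
        if np.issubdtype(v.dtype, np.floating):
            v.attrs["missing_value"] = np.nan
    return ds


def write_grid(path, grid: GridSpec, variables, extra_coords=None, attrs=None) -> None:
    ds = grid_to_dataset(grid, variables, extra_coords, attrs)
    ds.to_netcdf(path, engine=_ENGINE)


def read_grid(path) -> tuple[GridSpec, xr.Dataset]:
    """Read a gridded dataset, reconstructing its :class:`GridSpec`."""
    path = Path(path)
    try:
        ds = xr.load_dataset(path, engine=_ENGINE)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"cannot parse NetCDF file {path}: {exc}") from exc
    for name in ("lat", "lon"):
        if name not in ds.coords:
            raise ValueError(f"{path}: missing required coordinate '{name}'")
    lat = ds["lat"].values
    lon = ds["lon"].values
    dlat = float(ds.attrs.get("dlat", lat[1] - lat[0] if lat.size > 1 else 0.1))
    dlon = float(ds.attrs.get("dlon", lon[1] - lon[0] if lon.size > 1 else 0.1))
    grid = GridSpec(float(lat[0] - dlat / 2), float(lon[0] - dlon / 2),
                    lat.size, lon.size, dlat, dlon)
    return grid, ds


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path, required_columns: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot parse CSV file {path}: {exc}") from exc
    for col in required_columns:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(f"{path}: missing value for '{col}' in row {int(bad[0]) + 2}")
    return df
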