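"""QC filters, averaging-kernel correction and oversampling regridding."""

import numpy as np
import pytest

from satno2.grid import GridSpec
from satno2.observation_model import (
    DailyColumnField,
    apply_averaging_kernel_correction,
    apply_cloud_filter,
    apply_snow_filter,
    regrid_granule,
    snow_free_window,
)
from satno2.synthetic_world import DailyGranule


def make_granule(lon_lo, lon_hi, lat_lo, lat_hi, column, cloud=None, snow=None,
                 n_layers=3):
    column = np.asarray(column, dtype=float)
    f = column.size
    return DailyGranule(
        "test", 2000, 51,
        np.asarray(lon_lo, float), np.asarray(lon_hi, float),
        np.asarray(lat_lo, float), np.asarray(lat_hi, float),
        column,
        np.zeros(f) if cloud is None else np.asarray(cloud, float),
        np.zeros(f, bool) if snow is None else np.asarray(snow, bool),
        np.ones((f, n_layers)),
        np.tile([0.5, 0.3, 0.2], (f, 1)),
    )


# ----------------------------------------------------------------------
# cloud filter
# ----------------------------------------------------------------------
@pytest.mark.parametrize(
    "fractions, survivors",
    [
        ((0.4, 0.5, 0.6), 2),          # 0.5 kept under strict '>'
        (tuple(np.zeros(5)), 5),        # identity
        (tuple(np.arange(100) / 100.0), 51),  # 0.00..0.50 survive
    ],
)
def test_cloud_filter_threshold(fractions, survivors):
    n = len(fractions)
    g = make_granule(np.zeros(n), np.ones(n) * 0.1, np.zeros(n), np.ones(n) * 0.1,
                     np.ones(n), cloud=fractions)
    assert len(apply_cloud_filter(g)) == survivors


def test_cloud_filter_missing_fraction_rejected():
    g = make_granule([0, 0], [0.1, 0.1], [0, 0], [0.1, 0.1], [1.0, 2.0],
                     cloud=[np.nan, 0.2])
    out = apply_cloud_filter(g)
    assert len(out) == 1 and out.column[0] == 2.0


# ----------------------------------------------------------------------
# snow windows
# ----------------------------------------------------------------------
def _flags_from_free_runs(doys, free_runs):
    """(nyears, ndays) snow flags with the given snow-free doy intervals."""
    out = []
    for lo, hi in free_runs:
        out.append(~((doys >= lo) & (doys <= hi)))
    return np.stack(out)[:, :, None]  # one cell


def test_snow_window_never_snow_cell():
    doys = np.arange(1, 367)
    flags = np.zeros((2, doys.size, 1), dtype=bool)
    w = snow_free_window({0: flags[0], 1: flags[1]}, doys)
    assert w.start[0] == 1 and w.end[0] == 366


@pytest.mark.parametrize(
    "runs, expected",
    [
        ([(100, 300), (120, 280)], (120, 280)),
        ([(90, 310), (100, 300), (110, 290)], (110, 290)),
    ],
)
def test_snow_window_intersection_over_years(runs, expected):
    doys = np.arange(1, 367)
    flags = _flags_from_free_runs(doys, runs)
    w = snow_free_window({y: flags[y] for y in range(len(runs))}, doys)
    assert (w.start[0], w.end[0]) == expected


def test_snow_window_all_snow_year_empties_cell():
    doys = np.arange(1, 367)
    flags = _flags_from_free_runs(doys, [(100, 300)])
    all_snow = np.ones((doys.size, 1), dtype=bool)
    w = snow_free_window({0: flags[0], 1: all_snow}, doys)
    assert w.empty[0]


def test_snow_window_per_year_mode():
    doys = np.arange(1, 367)
    flags = _flags_from_free_runs(doys, [(100, 300), (120, 280)])
    ws = snow_free_window({0: flags[0], 1: flags[1]}, doys, mode="per-year")
    assert (ws[0].start[0], ws[0].end[0]) == (100, 300)
    assert (ws[1].start[0], ws[1].end[0]) == (120, 280)


def test_snow_filter_on_field_and_enumeration():
    g = GridSpec(0.0, 0.0, 2, 1)
    doys = np.arange(1, 367)
    # cell 0 free 110-290, cell 1 never snow
    flags = np.zeros((1, doys.size, 2, 1), dtype=bool)
    flags[0, :, 0, 0] = ~((doys >= 110) & (doys <= 290))
    w = snow_free_window({0: flags[0]}, doys)
    kept = 0
    for doy in (50, 120, 200, 300):
        field = DailyColumnField(2000, doy, "t", g, np.ones((2, 1)), np.ones((2, 1)))
        out = apply_snow_filter(field, w)
        if doy == 50 or doy == 300:
            assert np.isnan(out.values[0, 0]) and out.weight[0, 0] == 0
        else:
            assert out.values[0, 0] == 1.0
        assert out.values[1, 0] == 1.0  # never-snow cell untouched
        kept += int(~np.isnan(out.values[0, 0])) + 1
    assert kept == 6  # 2 cells x 4 days minus 2 snow-filtered observations


def test_filter_order_independence():
    n = 6
    g = make_granule(np.arange(n) * 0.1, np.arange(n) * 0.1 + 0.1,
                     np.zeros(n), np.full(n, 0.1),
                     np.arange(n, dtype=float),
                     cloud=[0.1, 0.9, 0.3, 0.8, 0.2, 0.6])
    grid = GridSpec(0.0, 0.0, 1, n)
    doys = np.arange(1, 367)
    flags = np.zeros((1, doys.size, 1, n), dtype=bool)
    flags[0, :, 0, :3] = True  # first three columns always snowy
    w = snow_free_window({0: flags[0]}, doys)
    a = apply_snow_filter(apply_cloud_filter(g), w, grid=grid)
    b = apply_cloud_filter(apply_snow_filter(g, w, grid=grid))
    np.testing.assert_array_equal(a.column, b.column)


# ----------------------------------------------------------------------
# averaging-kernel correction
# ----------------------------------------------------------------------
@pytest.mark.parametrize(
    "column, kernel, profile, expected",
    [
        (3.0, (1, 1, 1), (0.7, 0.2, 0.1), 3.0),       # unit kernel -> identity
        (3.0, (0.5, 1, 1), (2, 1, 1), 4.0),           # factor 4/3
        (2.0, (2, 1, 1), (1, 0, 0), 1.0),             # factor 0.5
    ],
)
def test_kernel_correction_arithmetic(column, kernel, profile, expected):
    got = apply_averaging_kernel_correction(column, kernel, profile)
    np.testing.assert_allclose(got, expected, rtol=1e-12)


def test_kernel_correction_scale_equivariant(rng):
    kernel = rng.uniform(0.5, 1.5, 4)
    x = rng.uniform(0.1, 2.0, 4)
    a = apply_averaging_kernel_correction(1.0, kernel, x)
    b = apply_averaging_kernel_correction(1.0, kernel, 2.0 * x)
    np.testing.assert_allclose(a, b, rtol=1e-12)


def test_kernel_correction_invalid_denominator_flagged():
    out = apply_averaging_kernel_correction(1.0, (-1, -1, -1), (1, 1, 1))
    assert np.isnan(out)
    with pytest.raises(ValueError):
        apply_averaging_kernel_correction(1.0, (1, 1), (1, 1, 1))


# ----------------------------------------------------------------------
# regridding
# ----------------------------------------------------------------------
def test_regrid_footprint_covering_four_cells_exactly():
    grid = GridSpec(0.0, 0.0, 2, 2)
    g = make_granule([0.0], [0.2], [0.0], [0.2], [5.0])
    out = regrid_granule(g, grid)
    np.testing.assert_allclose(out.values, 5.0)
    np.testing.assert_allclose(out.weight,
                               grid.cell_area[:, None] * np.ones((2, 2)), rtol=1e-12)


def test_regrid_overlapping_footprints_weighted_mean():
    """Overlap areas a and 3a with columns 2 and 6 -> (2a + 18a)/4a = 5."""
    grid = GridSpec(0.0, 0.0, 1, 1)
    g = make_granule([0.0, 0.025], [0.025, 0.1], [0.0, 0.0], [0.1, 0.1], [2.0, 6.0])
    out = regrid_granule(g, grid)
    np.testing.assert_allclose(out.values[0, 0], 5.0, rtol=1e-12)


def test_regrid_half_cell_footprint():
    grid = GridSpec(0.0, 0.0, 1, 1)
    g = make_granule([0.0], [0.05], [0.0], [0.1], [7.0])
    out = regrid_granule(g, grid)
    np.testing.assert_allclose(out.values[0, 0], 7.0)
    np.testing.assert_allclose(out.weight[0, 0], grid.cell_area[0] / 2, rtol=1e-12)


def test_regrid_uniform_columns_give_uniform_field(rng):
    grid = GridSpec(40.0, 10.0, 8, 8)
    lon_lo = rng.uniform(10.0, 10.6, 15)
    lat_lo = rng.uniform(40.0, 40.6, 15)
    g = make_granule(lon_lo, lon_lo + 0.2, lat_lo, lat_lo + 0.2, np.full(15, 3.3))
    out = regrid_granule(g, grid)
    covered = out.weight > 0
    np.testing.assert_allclose(out.values[covered], 3.3, rtol=1e-12)
    assert np.isnan(out.values[~covered]).all()


def test_regrid_matches_brute_force_loop(rng):
    """Oracle equivalence on a small grid: vectorised regridding equals an
    independent per-cell loop over all footprints to 1e-10."""
    grid = GridSpec(35.0, -3.0, 20, 30)
    n = 40
    lon_lo = rng.uniform(-3.0, -0.5, n)
    lat_lo = rng.uniform(35.0, 36.5, n)
    lon_hi = lon_lo + rng.uniform(0.05, 1.2, n)
    lat_hi = lat_lo + rng.uniform(0.05, 0.5, n)
    col = rng.uniform(0.5, 10.0, n)
    g = make_granule(lon_lo, np.minimum(lon_hi, 0.0), lat_lo,
                     np.minimum(lat_hi, 37.0), col)
    out = regrid_granule(g, grid, min_overlap_frac=0.0)

    values = np.full(grid.shape, np.nan)
    for i in range(grid.nlat):
        for j in range(grid.nlon):
            num = den = 0.0
            for f in range(n):
                ox = min(g.lon_hi[f], grid.lon_edges[j + 1]) - max(g.lon_lo[f], grid.lon_edges[j])
                oy = min(g.lat_hi[f], grid.lat_edges[i + 1]) - max(g.lat_lo[f], grid.lat_edges[i])
                if ox > 0 and oy > 0:
                    w = ox * oy * grid.coslat[i]
                    num += w * col[f]
                    den += w
            if den > 0:
                values[i, j] = num / den
    ok = ~np.isnan(values)
    assert (ok == ~np.isnan(out.values)).all()
    np.testing.assert_allclose(out.values[ok], values[ok], rtol=1e-10)
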