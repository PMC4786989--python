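"""The synthetic world must be deterministic, conservative, and obey its
closed-form contracts (geometric trends, exact ratio algebra, brute-force
footprint integrals)."""

import dataclasses

import numpy as np
import pytest

from satno2.synthetic_world import (
    CloudConfig,
    Hotspot,
    ScenarioConfig,
    make_ctm_surrogate,
    make_population,
    make_stations,
    make_truth_scenario,
    simulate_granules,
)


def small_config(**kw):
    base = dict(seed=7)
    base.update(kw)
    return ScenarioConfig(**base)


# ----------------------------------------------------------------------
# truth scenario
# ----------------------------------------------------------------------
def test_identity_case_uniform_world():
    cfg = small_config(background=1.0, hotspots=[], seasonal_amplitude=0.0,
                       interannual_sd=0.0,
                       region_trends={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0})
    truth = make_truth_scenario(cfg)
    for year, doy in [(1996, 1), (2004, 181), (2012, 361)]:
        np.testing.assert_array_equal(truth.surface_truth(year, doy).values, 1.0)


def test_geometric_regional_growth_closed_form():
    """+6.7%/year over 17 years: final-year regional mean = first x 1.067^16."""
    cfg = small_config(interannual_sd=0.0)
    truth = make_truth_scenario(cfg)
    first = truth.annual_mean_surface(1996, anomalies=False).values
    last = truth.annual_mean_surface(2012, anomalies=False).values
    sel = truth.regions.cells(1)
    np.testing.assert_allclose(last[sel] / first[sel], 1.067**16, rtol=1e-12)
    sel2 = truth.regions.cells(2)
    np.testing.assert_allclose(last[sel2] / first[sel2], (1 - 0.047) ** 16, rtol=1e-12)


def test_time_invariance_without_seasonality_and_trends():
    cfg = small_config(seasonal_amplitude=0.0, interannual_sd=0.0,
                       region_trends={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0})
    truth = make_truth_scenario(cfg)
    a = truth.surface_truth(1996, 1).values
    b = truth.surface_truth(2010, 181).values
    np.testing.assert_array_equal(a, b)


def test_truth_nonnegative_all_days(default_result):
    truth = default_result.truth
    for doy in truth.config.doys[::12]:
        assert (truth.surface_truth(2000, int(doy)).values >= 0).all()


def test_determinism_bit_identical():
    cfg = small_config()
    t1, t2 = make_truth_scenario(cfg), make_truth_scenario(small_config())
    np.testing.assert_array_equal(t1.surface_truth(2000, 51).values,
                                  t2.surface_truth(2000, 51).values)
    c1, c2 = make_ctm_surrogate(t1), make_ctm_surrogate(t2)
    s = t1.config.sensor("sciamachy")
    g1 = next(iter(simulate_granules(t1, c1, s, [2004])))
    g2 = next(iter(simulate_granules(t2, c2, s, [2004])))
    np.testing.assert_array_equal(g1.column, g2.column)
    np.testing.assert_array_equal(g1.cloud_frac, g2.cloud_frac)
    st1 = make_stations(t1, 5)
    st2 = make_stations(t2, 5)
    for a, b in zip(st1, st2):
        assert (a.lat, a.lon, a.site_class, a.bias) == (b.lat, b.lon, b.site_class, b.bias)
        np.testing.assert_array_equal(a.values, b.values)


def test_hotspot_validation():
    with pytest.raises(ValueError):
        Hotspot(34.0, 2.0, -1.0, 0.3)
    with pytest.raises(ValueError):
        Hotspot(34.0, 2.0, 1.0, 0.0)


# ----------------------------------------------------------------------
# surrogate CTM
# ----------------------------------------------------------------------
def test_uniform_field_algebra():
    """Uniform surface 2 ppb and ratio 0.5 ppb/1e15 -> column 4e15."""
    cfg = small_config(background=2.0, hotspots=[], seasonal_amplitude=0.0,
                       interannual_sd=0.0, ratio_base=0.5, ratio_variation=0.0,
                       region_trends={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0})
    ctm = make_ctm_surrogate(make_truth_scenario(cfg))
    np.testing.assert_allclose(ctm.column_field(2000, 51).values, 4.0, rtol=1e-12)


def test_profile_layers_sum_to_column(default_result):
    ctm = default_result.ctm
    col = ctm.column_field(2001, 101).values
    prof = ctm.profile(1, 2, 2001, 101)
    assert prof.size == default_result.config.scenario.n_layers
    np.testing.assert_allclose(prof.sum(), col[1, 2], rtol=1e-12)


def test_ratio_surface_column_consistency(default_result):
    ctm = default_result.ctm
    surf = ctm.surface_field(2005, 201).values
    col = ctm.column_field(2005, 201).values
    np.testing.assert_allclose(ctm.ratio * col, surf, rtol=1e-12)


def test_coarse_cell_is_area_mean_of_fine_cells(default_result):
    truth, ctm = default_result.truth, default_result.ctm
    fine = truth.surface_truth(2000, 51).values
    coarse = ctm.surface_field(2000, 51).values
    # brute force: cos-lat-weighted mean over the enclosed 0.1-degree cells
    i, j = 1, 2
    blk = fine[i * ctm.flat:(i + 1) * ctm.flat, j * ctm.flon:(j + 1) * ctm.flon]
    w = truth.grid.coslat[i * ctm.flat:(i + 1) * ctm.flat]
    expect = (blk * w[:, None]).sum() / (w.sum() * ctm.flon)
    np.testing.assert_allclose(coarse[i, j], expect, rtol=1e-12)


# ----------------------------------------------------------------------
# granules
# ----------------------------------------------------------------------
def test_noise_free_uniform_truth_gives_uniform_columns():
    cfg = small_config(background=1.5, hotspots=[], seasonal_amplitude=0.0,
                       interannual_sd=0.0, ratio_variation=0.0,
                       region_trends={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0},
                       cloud=CloudConfig(0.0, 0.0, 4.0))
    cfg = dataclasses.replace(cfg, sensors=[
        dataclasses.replace(s, noise_sd=0.0, bias=1.0, kernel_shape=0.0)
        for s in cfg.sensors])
    truth = make_truth_scenario(cfg)
    ctm = make_ctm_surrogate(truth)
    expected = 1.5 / cfg.ratio_base
    for g in simulate_granules(truth, ctm, cfg.sensor("gome"), [1999]):
        np.testing.assert_allclose(g.column, expected, rtol=1e-12)
        if g.doy > 30:
            break


def test_footprint_means_match_brute_force_integration(default_result):
    """Coarse and fine footprints centred on a hotspot: simulator columns
    equal a direct rectangle integral, and the coarse mean is smaller."""
    truth, ctm = default_result.truth, default_result.ctm
    cfg = truth.config
    col = ctm.fine_column_truth(2002, 1)
    g = truth.grid
    h = max(cfg.hotspots, key=lambda h: h.peak)

    def brute(lon0, lon1, lat0, lat1):
        num = den = 0.0
        for i in range(g.nlat):
            oy = min(lat1, g.lat_edges[i + 1]) - max(lat0, g.lat_edges[i])
            if oy <= 0:
                continue
            for j in range(g.nlon):
                ox = min(lon1, g.lon_edges[j + 1]) - max(lon0, g.lon_edges[j])
                if ox <= 0:
                    continue
                w = ox * oy * g.coslat[i]
                num += w * col[i, j]
                den += w
        return num / den

    from satno2.geometry import footprint_means, overlap_matrices

    coarse_rect = (h.lon - 1.6, h.lon + 1.6, h.lat - 0.2, h.lat + 0.2)
    fine_rect = (h.lon - 0.3, h.lon + 0.3, h.lat - 0.15, h.lat + 0.15)
    for rect in (coarse_rect, fine_rect):
        olat, olon = overlap_matrices(g, *[np.array([v]) for v in rect], min_frac=0.0)
        got = footprint_means(g, col, olat, olon)[0]
        np.testing.assert_allclose(got, brute(*rect), rtol=1e-10)
    olat_c, olon_c = overlap_matrices(g, *[np.array([v]) for v in coarse_rect])
    olat_f, olon_f = overlap_matrices(g, *[np.array([v]) for v in fine_rect])
    coarse_mean = footprint_means(g, col, olat_c, olon_c)[0]
    fine_mean = footprint_means(g, col, olat_f, olon_f)[0]
    assert coarse_mean < fine_mean  # the resolution contrast driving downscaling


def test_revisit_schedule_covers_every_cell(default_result):
    """Over `revisit` consecutive days every cell is observed at least once."""
    truth, ctm = default_result.truth, default_result.ctm
    cfg = truth.config
    from satno2.observation_model import regrid_granule

    for name in ("gome", "sciamachy"):
        sensor = cfg.sensor(name)
        seen = np.zeros(truth.grid.shape, dtype=bool)
        for k, g in enumerate(simulate_granules(truth, ctm, sensor,
                                                [sensor.era[0]])):
            seen |= regrid_granule(g, truth.grid).weight > 0
            if k + 1 >= sensor.revisit:
                break
        assert seen.all()


def test_footprints_stay_inside_grid(default_result):
    truth, ctm = default_result.truth, default_result.ctm
    g = truth.grid
    gr = next(iter(simulate_granules(truth, ctm, truth.config.sensor("gome"), [1996])))
    assert (gr.lon_lo >= g.lon0 - 1e-9).all() and (gr.lon_hi <= g.lon1 + 1e-9).all()
    assert (gr.lat_lo >= g.lat0 - 1e-9).all() and (gr.lat_hi <= g.lat1 + 1e-9).all()
    assert ((gr.cloud_frac >= 0) & (gr.cloud_frac <= 1)).all()


def test_date_outside_era_refused(default_result):
    truth, ctm = default_result.truth, default_result.ctm
    with pytest.raises(ValueError, match="era 1996-2003"):
        list(simulate_granules(truth, ctm, truth.config.sensor("gome"), [2005]))


# ----------------------------------------------------------------------
# population, regions, stations
# ----------------------------------------------------------------------
def test_population_totals_conserved_and_nonnegative(default_result):
    cfg = default_result.config.scenario
    pop = make_population(cfg, default_result.truth)
    pc = cfg.population
    f = pc.fine_factor
    for y in pop.years:
        assert (pop.counts[y] >= 0).all()
    # aggregating to any coarser grid conserves the total exactly
    c = pop.counts[2005]
    coarse = c.reshape(c.shape[0] // 4, 4, c.shape[1] // 4, 4).sum(axis=(1, 3))
    np.testing.assert_allclose(coarse.sum(), c.sum(), rtol=1e-12)
    # growth between snapshots follows the configured regional %/year
    r1 = default_result.regions.cells(1)
    g1 = pc.growth_pct[1]
    np.testing.assert_allclose(
        pop.counts[2000][r1].sum() / pop.counts[1995][r1].sum(),
        (1 + g1 / 100.0) ** 5, rtol=1e-9)


def test_region_mask_partitions_grid(default_result):
    regions = default_result.regions
    assert set(np.unique(regions.ids)) == {1, 2, 3, 4}
    assert regions.region_ids() == [1, 2, 3, 4]


def test_unbiased_station_reproduces_truth_cell_series(default_result):
    truth = default_result.truth
    st = make_stations(truth, 1, classes=["urban"])[0]
    i, j = truth.grid.locate(st.lat, st.lon)
    np.testing.assert_allclose(st.values, truth.cell_series(i, j) * st.bias,
                               rtol=1e-12)
    # bias 1.0 -> station annual mean equals the truth cell annual mean
    unbiased = st.values / st.bias
    np.testing.assert_allclose(unbiased.mean(axis=1),
                               truth.cell_series(i, j).mean(axis=1), rtol=1e-12)


def test_station_count_validation(default_result):
    with pytest.raises(ValueError):
        make_stations(default_result.truth, 0)
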