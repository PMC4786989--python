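"""End-to-end orchestration: simulate -> ingest -> harmonize -> surface
-> metrics -> trends.

:func:`run_pipeline` executes the whole chain in memory (optionally
persisting stage outputs and resuming from them) and returns a result
bundle carrying the harmonized record, the surface record, PWM series,
trend tables, the matching deterministic-truth trends, and continuity
diagnostics.  Every threshold defaults to the study value (cloud
radiance fraction 0.5, five valid days, 3.2 x 0.4 degree smoothing
window, reference periods 2003-2005 and 2007-2011, alpha 0.01).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exposure_metrics import interpolate_population, pwm, pwm_table
from .harmonization import HarmonizedRecord, boundary_zscores, build_harmonized_record
from .observation_model import (
    accumulate_annual,
    apply_cloud_filter,
    apply_snow_filter,
    correct_granule,
    regrid_granule,
    snow_free_window,
)
from .surface_estimation import SurfaceRecord, build_surface_record
from .synthetic_world import (
    CtmSurrogate,
    PopulationSeries,
    RegionMask,
    ScenarioConfig,
    TruthScenario,
    block_repeat,
    make_ctm_surrogate,
    make_population,
    make_stations,
    make_truth_scenario,
    simulate_granules,
)
from .trends import StationRules, compare_with_stations, ols_trend, trend_table

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_outputs"]

log = logging.getLogger(__name__)

DEFAULT_ERA_ASSIGNMENT = {
    "gome": (1996, 2003),
    "sciamachy": (2004, 2011),
    "gome2": (2012, 2012),
}


@dataclass
class PipelineConfig:
    """Scenario plus every QC/harmonization/trend threshold."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    cloud_max: float = 0.5
    min_days: int = 5
    snow_mode: str = "intersection"
    correct_sampling: bool = True
    reference_sensor: str = "sciamachy"
    era_assignment: dict[str, tuple[int, int]] | None = None
    ref_downscale: tuple[int, int] = (2003, 2005)
    ref_crosscal: tuple[int, int] = (2007, 2011)
    boxcar_window: tuple[float, float] = (3.2, 0.4)
    smoothing: str = "sensor"  # "sensor" (observation operator) or "boxcar"
    alpha: float = 0.01
    subperiods: list[tuple[int, int]] = field(default_factory=list)
    compare_stations: bool = True

    def resolved_assignment(self) -> dict[str, tuple[int, int]]:
        if self.era_assignment is not None:
            return self.era_assignment
        y0, y1 = self.scenario.years
        out = {}
        for name, (a, b) in DEFAULT_ERA_ASSIGNMENT.items():
            if any(s.name == name for s in self.scenario.sensors):
                out[name] = (max(a, y0), min(b, y1))
        return out

    def to_dict(self) -> dict:
        d = {
            "scenario": self.scenario.to_dict(),
            "cloud_max": self.cloud_max,
            "min_days": self.min_days,
            "snow_mode": self.snow_mode,
            "correct_sampling": self.correct_sampling,
            "reference_sensor": self.reference_sensor,
            "era_assignment": self.era_assignment,
            "ref_downscale": list(self.ref_downscale),
            "ref_crosscal": list(self.ref_crosscal),
            "boxcar_window": list(self.boxcar_window),
            "smoothing": self.smoothing,
            "alpha": self.alpha,
            "subperiods": [list(s) for s in self.subperiods],
            "compare_stations": self.compare_stations,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["scenario"] = ScenarioConfig.from_dict(d["scenario"])
        for key in ("ref_downscale", "ref_crosscal", "boxcar_window"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("era_assignment"):
            d["era_assignment"] = {k: tuple(v) for k, v in d["era_assignment"].items()}
        d["subperiods"] = [tuple(s) for s in d.get("subperiods", [])]
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    truth: TruthScenario
    ctm: CtmSurrogate
    population: PopulationSeries
    regions: RegionMask
    annuals: dict[str, dict[int, np.ndarray]]
    record: HarmonizedRecord
    surface: SurfaceRecord
    pwm_frame: pd.DataFrame
    trends_frame: pd.DataFrame
    truth_trends: pd.DataFrame
    station_frame: pd.DataFrame
    valid_masks: dict[int, np.ndarray]
    continuity_frac: float
    counters: dict[str, int]
    manifest: dict


def _needed_years(cfg: PipelineConfig, sensor_name: str, era: tuple[int, int]) -> list[int]:
    assignment = cfg.resolved_assignment()
    years: set[int] = set()
    a, b = assignment.get(sensor_name, (1, 0))
    years.update(range(a, b + 1))
    if sensor_name == cfg.reference_sensor:
        years.update(range(cfg.ref_downscale[0], cfg.ref_downscale[1] + 1))
        years.update(range(cfg.ref_crosscal[0], cfg.ref_crosscal[1] + 1))
    else:
        ref_start = assignment.get(cfg.reference_sensor, (0, 0))[0]
        if a > ref_start:  # late-era sensor needs its cross-calibration overlap
            years.update(range(cfg.ref_crosscal[0], cfg.ref_crosscal[1] + 1))
    return sorted(y for y in years if era[0] <= y <= era[1])


def ingest(cfg: PipelineConfig, truth: TruthScenario, ctm: CtmSurrogate):
    """Simulate and QC all sensor granules; aggregate to annual means.

    Returns ``(annuals, weights, ndays, valid, counters)`` where
    ``valid[sensor][year]`` is the (ndays, nlat, nlon) retrieval mask.
    """
    grid = truth.grid
    doys = cfg.scenario.doys
    flags = {y: truth.snow_flags(y)[:, :, None] & np.ones(grid.nlon, bool)[None, None, :]
             for y in cfg.scenario.year_list}
    window = snow_free_window(flags, doys, mode=cfg.snow_mode)
    if cfg.snow_mode == "per-year":
        windows = window
    annuals: dict[str, dict[int, np.ndarray]] = {}
    weights: dict[str, dict[int, np.ndarray]] = {}
    ndays: dict[str, dict[int, np.ndarray]] = {}
    valid: dict[str, dict[int, np.ndarray]] = {}
    ctm_wsum: dict[str, dict[int, np.ndarray]] = {}
    counters = {"footprints": 0, "cloud_rejected": 0, "snow_rejected": 0}
    for sensor in cfg.scenario.sensors:
        years = _needed_years(cfg, sensor.name, sensor.era)
        if not years:
            continue
        t0 = time.perf_counter()
        for d in (annuals, weights, ndays, valid, ctm_wsum):
            d[sensor.name] = {}
        daily_buffer = []
        ctm_acc = np.zeros(grid.shape)
        base_fine = block_repeat(ctm.surface_year_base(years[0]), ctm.flat, ctm.flon)
        current_year = years[0]

        def _flush(year, buffer, ctm_acc):
            mean, wsum, nd, vmask = accumulate_annual(buffer)
            annuals[sensor.name][year] = mean
            weights[sensor.name][year] = wsum
            ndays[sensor.name][year] = nd
            valid[sensor.name][year] = vmask
            ctm_wsum[sensor.name][year] = ctm_acc

        for granule in simulate_granules(truth, ctm, sensor, years):
            if granule.year != current_year:
                _flush(current_year, daily_buffer, ctm_acc)
                daily_buffer = []
                ctm_acc = np.zeros(grid.shape)
                current_year = granule.year
                base_fine = block_repeat(ctm.surface_year_base(current_year),
                                         ctm.flat, ctm.flon)
            n0 = len(granule)
            counters["footprints"] += n0
            granule = apply_cloud_filter(granule, cfg.cloud_max)
            counters["cloud_rejected"] += n0 - len(granule)
            n1 = len(granule)
            w = windows[granule.year] if cfg.snow_mode == "per-year" else window
            granule = apply_snow_filter(granule, w, grid=grid)
            counters["snow_rejected"] += n1 - len(granule)
            granule = correct_granule(granule)
            field = regrid_granule(granule, grid)
            # model surface on this day, weighted like the annual mean:
            # input to the observation-weighted sampling correction
            s_d = float(truth.seasonal_factor(granule.doy))
            ctm_acc += field.weight * (base_fine * s_d)
            daily_buffer.append(field)
        _flush(current_year, daily_buffer, ctm_acc)
        log.info("ingested %s years %s in %.1fs", sensor.name, years,
                 time.perf_counter() - t0)
    return annuals, weights, ndays, valid, ctm_wsum, counters


def coarse_sensor_name(cfg: PipelineConfig) -> str | None:
    """The downscaled (pre-reference-era) sensor, if any."""
    assignment = cfg.resolved_assignment()
    ref_start = assignment[cfg.reference_sensor][0]
    for name, (a, b) in assignment.items():
        if name != cfg.reference_sensor and b < ref_start:
            return name
    return None


def smoothed_reference_field(cfg: PipelineConfig, truth: TruthScenario,
                             annuals: dict[str, dict[int, np.ndarray]]):
    """Reference-period mean smeared by the coarse sensor's own operator.

    Returns None under ``smoothing="boxcar"`` (the harmonization then
    uses the footprint-sized boxcar); under the default ``"sensor"``
    smoothing the coarse sensor's deterministic offset cycle is
    enumerated, which reproduces its long-term smearing kernel exactly
    and avoids a resolution-mismatch step at the sensor boundary.
    """
    if cfg.smoothing == "boxcar":
        return None
    if cfg.smoothing != "sensor":
        raise ValueError("smoothing must be 'sensor' or 'boxcar'")
    from .observation_model import sensor_smooth

    coarse = coarse_sensor_name(cfg)
    if coarse is None:
        return None
    ref = annuals[cfg.reference_sensor]
    fine_ref = np.nanmean(np.stack(
        [ref[y] for y in range(cfg.ref_downscale[0], cfg.ref_downscale[1] + 1)]
    ), axis=0)
    return sensor_smooth(fine_ref, truth.grid, cfg.scenario.sensor(coarse))


def _assigned_sensor(cfg: PipelineConfig, year: int) -> str:
    for name, (a, b) in cfg.resolved_assignment().items():
        if a <= year <= b:
            return name
    raise ValueError(f"year {year} assigned to no sensor")


def sampling_factors(cfg: PipelineConfig, truth: TruthScenario, ctm: CtmSurrogate,
                     valid: dict[str, dict[int, np.ndarray]],
                     weights: dict[str, dict[int, np.ndarray]],
                     ctm_wsum: dict[str, dict[int, np.ndarray]],
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per record-year correction factors and valid-day counts.

    The factor compares the surrogate's all-day surface mean with its
    mean under the same observation weights the annual column mean used
    (each year's assigned sensor), so continuous down-weighting of
    cloudy-season days is corrected, not only wholly missing days.
    """
    years = cfg.scenario.year_list
    grid = truth.grid
    s = np.asarray(truth.seasonal_factor(cfg.scenario.doys))
    factors = np.ones((len(years), *grid.shape))
    nd = np.zeros((len(years), *grid.shape), dtype=int)
    for k, year in enumerate(years):
        sensor = _assigned_sensor(cfg, year)
        nd[k] = valid[sensor][year].sum(axis=0)
        if cfg.correct_sampling:
            base_fine = block_repeat(ctm.surface_year_base(year), ctm.flat, ctm.flon)
            all_mean = base_fine * float(s.mean())
            wsum = weights[sensor][year]
            with np.errstate(invalid="ignore", divide="ignore"):
                w_mean = ctm_wsum[sensor][year] / wsum
                f = all_mean / w_mean
            factors[k] = np.where(wsum > 0, f, 1.0)
    return factors, nd


def truth_trend_table(truth: TruthScenario, population: PopulationSeries,
                      regions: RegionMask, anomalies: bool = False) -> pd.DataFrame:
    """OLS relative trends of the truth PWM series (deterministic truth by
    default) — the recovery target for the estimated regional trends."""
    years = truth.config.year_list
    rows = []
    for rid in regions.region_ids() + [0]:
        series = []
        for y in years:
            popy = interpolate_population(population, y)
            fieldy = truth.annual_mean_surface(y, anomalies=anomalies).values
            series.append(pwm(fieldy, popy, regions, None if rid == 0 else rid))
        est = ols_trend(np.array(years), np.array(series))
        rows.append({
            "region_id": rid,
            "region_name": "global" if rid == 0 else regions.names[rid],
            "rel_trend_pct": est.rel_trend, "slope_ppb_yr": est.slope,
            "mean_ppb": est.longterm_mean,
        })
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig | None = None, outdir=None,
                 resume: bool = False) -> PipelineResult:
    """Execute the full analysis chain on the configured synthetic world."""
    cfg = cfg or PipelineConfig()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    truth = make_truth_scenario(cfg.scenario)
    ctm = make_ctm_surrogate(truth)
    regions = truth.regions
    population = make_population(cfg.scenario, truth)
    grid = truth.grid

    annuals, weights, nd_sensor, valid, ctm_wsum, counters = ingest(cfg, truth, ctm)

    record = build_harmonized_record(
        annuals, grid,
        reference_sensor=cfg.reference_sensor,
        era_assignment=cfg.resolved_assignment(),
        ref_downscale=cfg.ref_downscale,
        ref_crosscal=cfg.ref_crosscal,
        years=cfg.scenario.years,
        boxcar_window=cfg.boxcar_window,
        smoothed_reference=smoothed_reference_field(cfg, truth, annuals),
    )

    factors, nd = sampling_factors(cfg, truth, ctm, valid, weights, ctm_wsum)
    fine_ratio = ctm.fine_ratio()
    surface = build_surface_record(record.years, record.fields, fine_ratio, grid,
                                   factors, nd, cfg.min_days)

    pwm_frame = pwm_table(surface.years, surface.surface, population, regions)
    trends_frame = trend_table(pwm_frame, cfg.alpha, cfg.subperiods)
    truth_trends = truth_trend_table(truth, population, regions)

    valid_by_year = {y: valid[_assigned_sensor(cfg, y)][y] for y in record.years}
    if cfg.compare_stations:
        stations = make_stations(truth)
        station_frame = compare_with_stations(
            record.years, surface.surface, grid, stations, valid_by_year, StationRules()
        )
    else:
        station_frame = pd.DataFrame()

    continuity_frac = _continuity(cfg, truth, surface)

    manifest = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.scenario.seed,
        "thresholds": {
            "cloud_max": cfg.cloud_max, "min_days": cfg.min_days,
            "alpha": cfg.alpha, "boxcar_window": list(cfg.boxcar_window),
        },
        "counters": counters,
        "provenance": {str(y): list(v) for y, v in record.provenance.items()},
    }
    result = PipelineResult(cfg, truth, ctm, population, regions, annuals, record,
                            surface, pwm_frame, trends_frame, truth_trends,
                            station_frame, valid_by_year, continuity_frac,
                            counters, manifest)
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def _continuity(cfg: PipelineConfig, truth: TruthScenario,
                surface: SurfaceRecord) -> float:
    """Fraction of hotspot ('major city') pixels whose sensor-boundary
    year-to-year jumps stay within 1.5 sd of that pixel's differences."""
    years = surface.years
    assignment = cfg.resolved_assignment()
    boundaries = []
    spans = sorted(assignment.values())
    for (_, b), (a2, _) in zip(spans, spans[1:]):
        if b + 1 == a2 and b in years:
            boundaries.append(years.index(b))
    if not boundaries or len(years) < 4 or not cfg.scenario.hotspots:
        return float("nan")
    cells = [truth.grid.locate(h.lat, h.lon) for h in cfg.scenario.hotspots]
    series = np.stack([surface.surface[:, i, j] for i, j in cells], axis=1)
    ok = ~np.isnan(series).any(axis=0)
    if not ok.any():
        return float("nan")
    _, frac = boundary_zscores(series[:, ok], boundaries)
    return frac


def write_outputs(result: PipelineResult, outdir) -> None:
    """Persist the report bundle: NetCDF fields, CSV tables, manifest."""
    from .io_utils import write_grid, write_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = result.truth.grid
    years = np.array(result.record.years)
    chash = result.config.config_hash()
    write_grid(outdir / "record.nc", grid,
               {"column": (("year", "lat", "lon"), result.record.fields)},
               extra_coords={"year": years},
               attrs={"config_hash": chash, "units": "1e15 molec cm-2"})
    write_grid(outdir / "surface.nc", grid,
               {
                   "surface": (("year", "lat", "lon"), result.surface.surface),
                   "factor": (("year", "lat", "lon"), result.surface.factors),
                   "ndays": (("year", "lat", "lon"), result.surface.ndays.astype(float)),
               },
               extra_coords={"year": years},
               attrs={"config_hash": chash, "units": "ppb"})
    for name, df in (("metrics.csv", result.pwm_frame),
                     ("trends.csv", result.trends_frame),
                     ("truth_trends.csv", result.truth_trends),
                     ("stations.csv", result.station_frame)):
        df = df.copy()
        df["config_hash"] = chash
        write_table(df, outdir / name)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    log.info("wrote report bundle to %s", outdir)
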