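"""Synthetic study world: truth fields, surrogate CTM, sensors, granules,
population, regions and ground stations.

This module generates, with known ground truth, every input that a real
satellite-based NO2 exposure study obtains externally:

* a fine-scale (0.1 degree) ground-level NO2 field with urban hotspots,
  a seasonal cycle, region-specific multiplicative annual trends and
  mild region-level interannual variability;
* a surrogate chemical-transport model at coarse resolution whose
  surface-to-column ratio links columns to surface concentrations
  exactly, plus layer profiles for averaging-kernel emulation;
* three sun-synchronous sensors with distinct rectangular footprints,
  overlapping observation eras, revisit schedules, multiplicative
  retrieval noise, cloud radiance fractions and high-latitude snow;
* gridded population snapshots at 5-year intervals, region masks, and
  point station records with local multiplicative bias.

Because the truth is synthetic and closed-form, every downstream stage
of the pipeline (regridding, harmonization, surface conversion,
sampling-bias correction, trends) has a recoverable answer.

All randomness derives from a single master seed through named
``numpy.random.SeedSequence`` streams, so identical configurations give
bit-identical worlds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Iterator, Sequence

import numpy as np

from .geometry import footprint_means, overlap_matrices
from .grid import GridField, GridSpec

__all__ = [
    "Hotspot",
    "SensorSpec",
    "CloudConfig",
    "SnowConfig",
    "PopulationConfig",
    "StationConfig",
    "ScenarioConfig",
    "TruthScenario",
    "RegionMask",
    "CtmSurrogate",
    "DailyGranule",
    "PopulationSeries",
    "StationRecord",
    "default_sensors",
    "make_truth_scenario",
    "make_ctm_surrogate",
    "simulate_granules",
    "make_regions",
    "make_population",
    "make_stations",
]

DAYS_PER_YEAR = 365.0


# ----------------------------------------------------------------------
# configuration dataclasses
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class Hotspot:
    """A Gaussian urban enhancement of the surface field.

    ``peak`` is the added concentration at the centre [ppb]; ``decay``
    the Gaussian scale length in degrees.
    """

    lat: float
    lon: float
    peak: float
    decay: float

    def __post_init__(self) -> None:
        if self.peak < 0:
            raise ValueError("hotspot peak must be nonnegative")
        if self.decay <= 0:
            raise ValueError("hotspot decay length must be positive")


@dataclass(frozen=True)
class SensorSpec:
    """A synthetic column-observing sensor.

    ``footprint_lon``/``footprint_lat`` give the rectangular footprint in
    degrees (320 km x 40 km ~ 3.2 x 0.4 degrees at ~111 km/degree).
    ``revisit`` is the number of days needed to cover the full longitude
    extent.  ``noise_sd`` is the relative sd of multiplicative Gaussian
    retrieval noise, truncated so columns keep at least 10% of their
    value.  ``bias`` is a uniform multiplicative inter-sensor calibration
    offset.  ``sampling`` is ``"tile"`` (disjoint daily tiling, random
    per-day offsets) or ``"overlap"`` (footprints centred on a finer
    stride so the long-term mean approaches a uniform moving average,
    emulating orbit-position diversity of a coarse scanner).
    """

    name: str
    footprint_lon: float
    footprint_lat: float
    era: tuple[int, int]
    revisit: int
    overpass: tuple[float, float] = (10.0, 12.0)
    noise_sd: float = 0.25
    kernel_shape: float = 0.6
    bias: float = 1.0
    sampling: str = "tile"
    stride_lon: float = 0.0
    stride_lat: float = 0.0

    def kernel(self, n_layers: int) -> np.ndarray:
        """Averaging-kernel vector: reduced sensitivity near the surface.

        ``A_l = 1 + shape * (l/(L-1) - 1/2)`` with layer 0 at the surface;
        shape 0 gives the unit kernel.
        """
        if n_layers == 1:
            return np.ones(1)
        frac = np.arange(n_layers) / (n_layers - 1)
        return 1.0 + self.kernel_shape * (frac - 0.5)


def default_sensors() -> list[SensorSpec]:
    """The three-sensor constellation the study conditions assume.

    Footprints, eras, revisit periods and era overlaps mirror the
    GOME / SCIAMACHY / GOME-2 progression of heritage NO2 sounders.
    """
    return [
        SensorSpec(
            name="gome",
            footprint_lon=3.2,
            footprint_lat=0.4,
            era=(1996, 2003),
            revisit=3,
            overpass=(9.5, 11.5),
            noise_sd=0.30,
            sampling="overlap",
            stride_lon=0.4,
            stride_lat=0.2,
        ),
        SensorSpec(
            name="sciamachy",
            footprint_lon=0.6,
            footprint_lat=0.3,
            era=(2002, 2011),
            revisit=6,
            overpass=(9.0, 11.0),
            noise_sd=0.25,
        ),
        SensorSpec(
            name="gome2",
            footprint_lon=0.8,
            footprint_lat=0.4,
            era=(2007, 2012),
            revisit=1,
            overpass=(8.5, 10.5),
            noise_sd=0.25,
            bias=1.10,
        ),
    ]


@dataclass(frozen=True)
class CloudConfig:
    """Per-footprint cloud radiance fraction ~ Beta, seasonally varying.

    The mean interpolates sinusoidally between ``mean_summer`` and
    ``mean_winter`` (winter peak at the seasonal peak day), so QC losses
    correlate with season and the sampling-bias correction has something
    to correct.
    """

    mean_summer: float = 0.30
    mean_winter: float = 0.55
    concentration: float = 4.0


@dataclass(frozen=True)
class SnowConfig:
    """Snow poleward of a latitude threshold outside a day-of-year window."""

    lat_threshold: float = 50.0
    free_start: int = 110
    free_end: int = 290
    jitter_days: int = 10


@dataclass(frozen=True)
class PopulationConfig:
    """Gridded population: urban log-normal peaks plus rural background.

    Generated on a grid ``fine_factor`` times finer than the analysis
    grid, then aggregated by summation (conserving totals exactly) —
    the 2.5-arc-minute-to-0.1-degree structure of global population
    products.  ``growth_pct`` maps region id to %/year growth applied
    geometrically between snapshots.
    """

    snapshot_years: tuple[int, ...] = (1995, 2000, 2005, 2010, 2015)
    total: float = 5.0e7
    urban_fraction: float = 0.7
    urban_sigma: float = 0.25
    texture_sd: float = 0.4
    fine_factor: int = 2
    growth_pct: dict[int, float] = field(
        default_factory=lambda: {1: 1.2, 2: 0.3, 3: 0.5, 4: 0.8}
    )


@dataclass(frozen=True)
class StationConfig:
    n: int = 12
    class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "rural": 0.30,
            "suburban": 0.30,
            "urban": 0.30,
            "traffic": 0.10,
        }
    )
    bias_sd: float = 0.15


@dataclass
class ScenarioConfig:
    """Full description of the synthetic study conditions.

    Defaults define a 9.6 x 4.8 degree window at 0.1 degrees (the
    smallest extent commensurate with all three footprint sizes), four
    quadrant regions with trends echoing the strongest observed regional
    NO2 trajectories (+6.7, -4.7, -2.5, -2.1 %/year), a 35% seasonal
    cycle peaking in winter, 5% region-level interannual variability,
    and 73 sampled days per year (every 5th day — equally spaced so the
    seasonal cosine sums to exactly zero over a year).
    """

    lat0: float = 32.0
    lon0: float = 0.0
    nlat: int = 48
    nlon: int = 96
    cell: float = 0.1
    years: tuple[int, int] = (1996, 2012)
    day_step: int = 5
    background: float = 0.6
    hotspots: list[Hotspot] | None = None  # None -> per-region defaults; [] -> none
    region_blocks: tuple[int, int] = (2, 2)
    region_trends: dict[int, float] = field(
        default_factory=lambda: {1: 6.7, 2: -4.7, 3: -2.5, 4: -2.1}
    )
    seasonal_amplitude: float = 0.35
    seasonal_peak_doy: int = 15
    interannual_sd: float = 0.05
    model_res: tuple[float, float] = (2.4, 2.4)
    ratio_base: float = 0.4
    ratio_variation: float = 0.3
    n_layers: int = 3
    profile_fractions: tuple[float, ...] = (0.5, 0.3, 0.2)
    profile_coupling: float = 0.1
    sensors: list[SensorSpec] = field(default_factory=default_sensors)
    cloud: CloudConfig = field(default_factory=CloudConfig)
    snow: SnowConfig = field(default_factory=SnowConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    stations: StationConfig = field(default_factory=StationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hotspots is None:
            self.hotspots = _default_hotspots(self)
        eras = sorted((s.era for s in self.sensors), key=lambda e: e[0])
        for (a0, a1), (b0, b1) in zip(eras, eras[1:]):
            if b0 > a1:
                raise ValueError(
                    f"sensor eras must overlap by >= 1 year; gap between "
                    f"{(a0, a1)} and {(b0, b1)}"
                )

    # -- geometry helpers --------------------------------------------
    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.lat0, self.lon0, self.nlat, self.nlon, self.cell, self.cell)

    @property
    def doys(self) -> np.ndarray:
        return np.arange(1, 366, self.day_step)

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def sensor(self, name: str) -> SensorSpec:
        for s in self.sensors:
            if s.name == name:
                return s
        raise KeyError(f"no sensor named {name!r}")

    # -- serialization -----------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["hotspots"] = [asdict(h) for h in self.hotspots]
        d["sensors"] = [asdict(s) for s in self.sensors]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["hotspots"] = [Hotspot(**h) for h in d.get("hotspots", [])]
        d["sensors"] = [SensorSpec(**_tupled(s, "era", "overpass")) for s in d["sensors"]]
        d["cloud"] = CloudConfig(**d["cloud"])
        d["snow"] = SnowConfig(**d["snow"])
        pop = dict(d["population"])
        pop["growth_pct"] = {int(k): v for k, v in pop["growth_pct"].items()}
        pop["snapshot_years"] = tuple(pop["snapshot_years"])
        d["population"] = PopulationConfig(**pop)
        st = dict(d["stations"])
        d["stations"] = StationConfig(**st)
        d["region_trends"] = {int(k): v for k, v in d["region_trends"].items()}
        for key in ("years", "region_blocks", "model_res", "profile_fractions"):
            d[key] = tuple(d[key])
        return cls(**d)


def _tupled(d: dict, *keys: str) -> dict:
    d = dict(d)
    for k in keys:
        if k in d and d[k] is not None:
            d[k] = tuple(d[k])
    return d


def _default_hotspots(cfg: ScenarioConfig) -> list[Hotspot]:
    """Two hotspots per region, kept away from region borders so coarse
    footprints do not mix regions with different trends."""
    peaks = {1: (6.0, 4.0), 2: (9.0, 5.0), 3: (8.0, 4.0), 4: (10.0, 6.0)}
    nrow, ncol = cfg.region_blocks
    hlat = cfg.nlat * cfg.cell / nrow
    hlon = cfg.nlon * cfg.cell / ncol
    spots = []
    rid = 0
    for r in range(nrow):
        for c in range(ncol):
            rid += 1
            clat = cfg.lat0 + (r + 0.5) * hlat
            clon = cfg.lon0 + (c + 0.5) * hlon
            p1, p2 = peaks.get(rid, (6.0, 4.0))
            spots.append(Hotspot(clat + 0.35, clon - 0.55, p1, 0.45))
            spots.append(Hotspot(clat - 0.40, clon + 0.50, p2, 0.35))
    return spots


# ----------------------------------------------------------------------
# regions
# ----------------------------------------------------------------------
@dataclass
class RegionMask:
    """Integer region id per cell; 0 is reserved for 'no region'."""

    grid: GridSpec
    ids: np.ndarray
    names: dict[int, str]

    def region_ids(self) -> list[int]:
        return sorted(int(i) for i in np.unique(self.ids) if i != 0)

    def cells(self, region_id: int) -> np.ndarray:
        return self.ids == region_id


def make_regions(config: ScenarioConfig) -> RegionMask:
    """Block regions covering the window (GBD-style reporting units)."""
    nrow, ncol = config.region_blocks
    g = config.grid
    if g.nlat % nrow or g.nlon % ncol:
        raise ValueError("region blocks must divide the grid evenly")
    ids = np.zeros(g.shape, dtype=int)
    names = {}
    rid = 0
    for r in range(nrow):
        for c in range(ncol):
            rid += 1
            ids[
                r * (g.nlat // nrow) : (r + 1) * (g.nlat // nrow),
                c * (g.nlon // ncol) : (c + 1) * (g.nlon // ncol),
            ] = rid
            names[rid] = f"region-{rid}"
    return RegionMask(g, ids, names)


# ----------------------------------------------------------------------
# truth scenario
# ----------------------------------------------------------------------
class TruthScenario:
    """The synthetic atmosphere: closed-form daily surface NO2 truth.

    The surface field factorises as

        truth(cell, year, doy) = base(cell) * trend(region, year)
                                 * anomaly(region, year) * season(doy)

    with ``base`` = background + Gaussian hotspots, ``trend`` the
    configured geometric %/year growth, ``anomaly`` a mean-one lognormal
    interannual factor (sd ``interannual_sd``), and ``season`` a cosine
    with winter peak.  The factorisation makes annual means exact: over
    the equally spaced day grid the seasonal factor averages to exactly
    one, so the deterministic annual mean is ``base * trend``.
    """

    def __init__(self, config: ScenarioConfig):
        self.config = config
        self.grid = config.grid
        self.regions = make_regions(config)
        g = self.grid
        latc, lonc = np.meshgrid(g.lat_centers, g.lon_centers, indexing="ij")
        base = np.full(g.shape, config.background, dtype=float)
        for h in config.hotspots:
            d2 = (latc - h.lat) ** 2 + (lonc - h.lon) ** 2
            base += h.peak * np.exp(-d2 / (2.0 * h.decay**2))
        self.base = base

        # named random streams derived from the master seed
        ss = np.random.SeedSequence(config.seed)
        kids = ss.spawn(4)
        self._rng_anom = np.random.default_rng(kids[0])
        self._rng_snow = np.random.default_rng(kids[1])
        self.rng_population = np.random.default_rng(kids[2])
        self.rng_stations = np.random.default_rng(kids[3])
        self._sensor_seeds = {
            s.name: ss2 for s, ss2 in zip(config.sensors, ss.spawn(len(config.sensors) + 4)[4:])
        }

        years = config.year_list
        rids = self.regions.region_ids()
        sd = config.interannual_sd
        z = self._rng_anom.standard_normal((len(years), len(rids)))
        self._anom = {
            (y, r): float(np.exp(sd * z[i, j] - 0.5 * sd * sd))
            for i, y in enumerate(years)
            for j, r in enumerate(rids)
        }
        jit = config.snow.jitter_days
        if jit > 0:
            j1 = self._rng_snow.integers(-jit, jit + 1, size=len(years))
            j2 = self._rng_snow.integers(-jit, jit + 1, size=len(years))
        else:
            j1 = j2 = np.zeros(len(years), dtype=int)
        self._snow_bounds = {
            y: (config.snow.free_start + int(j1[i]), config.snow.free_end + int(j2[i]))
            for i, y in enumerate(years)
        }
        self._trend_cache: dict[int, np.ndarray] = {}

    # -- factor fields -----------------------------------------------
    def trend_factor_map(self, year: int) -> np.ndarray:
        """Per-cell multiplicative factor accumulated since the first year."""
        if year not in self._trend_cache:
            y0 = self.config.years[0]
            out = np.ones(self.grid.shape)
            for rid in self.regions.region_ids():
                pct = self.config.region_trends.get(rid, 0.0)
                out[self.regions.ids == rid] = (1.0 + pct / 100.0) ** (year - y0)
            self._trend_cache[year] = out
        return self._trend_cache[year]

    def anomaly_map(self, year: int) -> np.ndarray:
        out = np.ones(self.grid.shape)
        for rid in self.regions.region_ids():
            out[self.regions.ids == rid] = self._anom[(year, rid)]
        return out

    def seasonal_factor(self, doy) -> np.ndarray | float:
        a = self.config.seasonal_amplitude
        phase = 2.0 * np.pi * (np.asarray(doy, dtype=float) - self.config.seasonal_peak_doy)
        return 1.0 + a * np.cos(phase / DAYS_PER_YEAR)

    # -- truth fields ------------------------------------------------
    def year_base(self, year: int, anomalies: bool = True) -> np.ndarray:
        """Day-independent part of the truth for one year."""
        v = self.base * self.trend_factor_map(year)
        if anomalies:
            v = v * self.anomaly_map(year)
        return v

    def surface_truth(self, year: int, doy: int, anomalies: bool = True) -> GridField:
        """Midmorning (overpass-window) surface NO2 [ppb] for one day."""
        self._check_year(year)
        vals = self.year_base(year, anomalies) * float(self.seasonal_factor(doy))
        return GridField(self.grid, vals)

    def annual_mean_surface(self, year: int, anomalies: bool = True) -> GridField:
        """Mean over the scenario day grid; exact because the seasonal
        factor sums to zero over equally spaced days."""
        self._check_year(year)
        s = float(np.mean(self.seasonal_factor(self.config.doys)))
        return GridField(self.grid, self.year_base(year, anomalies) * s)

    def cell_series(self, i: int, j: int, anomalies: bool = True) -> np.ndarray:
        """(nyears, ndays) truth series at one cell."""
        s = self.seasonal_factor(self.config.doys)
        rows = [self.year_base(y, anomalies)[i, j] * s for y in self.config.year_list]
        return np.array(rows)

    # -- snow --------------------------------------------------------
    def snow_free_bounds(self, year: int) -> tuple[int, int]:
        self._check_year(year)
        return self._snow_bounds[year]

    def snow_flags(self, year: int) -> np.ndarray:
        """(ndays, nlat) boolean snow presence; constant in longitude."""
        lo, hi = self.snow_free_bounds(year)
        doys = self.config.doys
        snowy_day = (doys < lo) | (doys > hi)
        snowy_lat = self.grid.lat_centers >= self.config.snow.lat_threshold
        return snowy_day[:, None] & snowy_lat[None, :]

    def _check_year(self, year: int) -> None:
        y0, y1 = self.config.years
        if not (y0 <= year <= y1):
            raise ValueError(f"year {year} outside scenario years {y0}-{y1}")


def make_truth_scenario(config: ScenarioConfig) -> TruthScenario:
    """Build the deterministic-for-a-seed synthetic truth."""
    return TruthScenario(config)


# ----------------------------------------------------------------------
# surrogate chemical-transport model
# ----------------------------------------------------------------------
def _block_factors(fine: GridSpec, model_res: tuple[float, float]) -> tuple[int, int]:
    flat = model_res[0] / fine.dlat
    flon = model_res[1] / fine.dlon
    if abs(flat - round(flat)) > 1e-9 or abs(flon - round(flon)) > 1e-9:
        raise ValueError("model resolution must be an integer multiple of the fine cell")
    flat, flon = int(round(flat)), int(round(flon))
    if fine.nlat % flat or fine.nlon % flon:
        raise ValueError("model cells must tile the fine grid exactly")
    return flat, flon


def block_mean(values: np.ndarray, flat: int, flon: int, coslat: np.ndarray) -> np.ndarray:
    """Area-weighted (cos lat) mean over blocks of ``flat x flon`` cells."""
    nlat, nlon = values.shape
    w = np.broadcast_to(coslat[:, None], values.shape)
    vw = (values * w).reshape(nlat // flat, flat, nlon // flon, flon).sum(axis=(1, 3))
    ww = w.reshape(nlat // flat, flat, nlon // flon, flon).sum(axis=(1, 3))
    return vw / ww


def block_repeat(values: np.ndarray, flat: int, flon: int) -> np.ndarray:
    return np.repeat(np.repeat(values, flat, axis=0), flon, axis=1)


class CtmSurrogate:
    """Coarse-model stand-in linking surface NO2 to column densities.

    On its native (coarse) grid the surrogate enforces
    ``surface = ratio * column`` exactly: the ratio field [ppb per
    1e15 molec cm^-2] is a fixed, smoothly varying positive pattern and
    the column is defined as surface / ratio.  Layer partial-column
    profiles sum to the column by construction; the surface-layer
    fraction is mildly enhanced where the surface field is high
    (polluted boundary layers), which makes averaging-kernel effects
    spatially varying.
    """

    def __init__(self, truth: TruthScenario, model_res: tuple[float, float],
                 ratio_base: float, ratio_variation: float,
                 fractions: Sequence[float], coupling: float):
        if ratio_base <= 0:
            raise ValueError("ratio base must be positive")
        if not 0 <= ratio_variation < 1:
            raise ValueError("ratio variation must lie in [0, 1)")
        self.truth = truth
        fine = truth.grid
        self.flat, self.flon = _block_factors(fine, model_res)
        self.grid = GridSpec(
            fine.lat0, fine.lon0,
            fine.nlat // self.flat, fine.nlon // self.flon,
            model_res[0], model_res[1],
        )
        g = self.grid
        latn = (g.lat_centers - fine.lat0) / max(fine.nlat * fine.dlat, 1e-12)
        lonn = (g.lon_centers - fine.lon0) / max(fine.nlon * fine.dlon, 1e-12)
        pattern = np.sin(2 * np.pi * lonn)[None, :] * np.cos(np.pi * latn)[:, None]
        self.ratio = ratio_base * (1.0 + ratio_variation * pattern)

        base_c = block_mean(truth.base, self.flat, self.flon, fine.coslat)
        span = base_c.max() - base_c.min()
        norm = (base_c - base_c.mean()) / span if span > 0 else np.zeros_like(base_c)
        f = np.array(fractions, dtype=float)
        if f.ndim != 1 or f.size < 1 or np.any(f <= 0):
            raise ValueError("profile fractions must be positive")
        f = f / f.sum()
        fr = np.broadcast_to(f, (*base_c.shape, f.size)).copy()
        fr[..., 0] *= 1.0 + coupling * np.clip(2 * norm, -1, 1)
        self.fractions = fr / fr.sum(axis=-1, keepdims=True)

    # -- fields on the model grid ------------------------------------
    def surface_year_base(self, year: int, anomalies: bool = True) -> np.ndarray:
        return block_mean(
            self.truth.year_base(year, anomalies), self.flat, self.flon,
            self.truth.grid.coslat,
        )

    def surface_field(self, year: int, doy: int, anomalies: bool = True) -> GridField:
        vals = self.surface_year_base(year, anomalies) * float(
            self.truth.seasonal_factor(doy)
        )
        return GridField(self.grid, vals)

    def column_field(self, year: int, doy: int, anomalies: bool = True) -> GridField:
        surf = self.surface_field(year, doy, anomalies).values
        if np.any((self.ratio <= 0) & (surf != 0)):
            raise ValueError("zero/negative ratio with nonzero surface")
        return GridField(self.grid, surf / self.ratio)

    def ratio_field(self) -> GridField:
        return GridField(self.grid, self.ratio.copy())

    def profile(self, i: int, j: int, year: int, doy: int) -> np.ndarray:
        """Layer partial columns at one model cell; sums to the column."""
        col = self.column_field(year, doy).values[i, j]
        return self.fractions[i, j] * col

    # -- fine-grid views ---------------------------------------------
    def fine_ratio(self) -> np.ndarray:
        """Ratio resampled to the truth grid by block (nearest) assignment."""
        return block_repeat(self.ratio, self.flat, self.flon)

    def fine_column_truth(self, year: int, doy: int, anomalies: bool = True) -> np.ndarray:
        """True 0.1-degree column: fine surface divided by the model ratio."""
        surf = self.truth.surface_truth(year, doy, anomalies).values
        return surf / self.fine_ratio()

    def distortion(self, kernel: np.ndarray) -> np.ndarray:
        """Per-model-cell retrieval distortion factor sum(A * f)."""
        return np.einsum("ijl,l->ij", self.fractions, kernel)


def make_ctm_surrogate(
    truth: TruthScenario,
    model_res: tuple[float, float] | None = None,
    ratio_base: float | None = None,
    ratio_variation: float | None = None,
) -> CtmSurrogate:
    cfg = truth.config
    return CtmSurrogate(
        truth,
        model_res or cfg.model_res,
        cfg.ratio_base if ratio_base is None else ratio_base,
        cfg.ratio_variation if ratio_variation is None else ratio_variation,
        cfg.profile_fractions,
        cfg.profile_coupling,
    )


# ----------------------------------------------------------------------
# granules
# ----------------------------------------------------------------------
@dataclass
class DailyGranule:
    """One sensor-day of footprint observations."""

    sensor: str
    year: int
    doy: int
    lon_lo: np.ndarray
    lon_hi: np.ndarray
    lat_lo: np.ndarray
    lat_hi: np.ndarray
    column: np.ndarray
    cloud_frac: np.ndarray
    snow: np.ndarray
    kernel: np.ndarray   # (F, L)
    apriori: np.ndarray  # (F, L) model partial-column profile (relative scale)

    def __len__(self) -> int:
        return int(self.column.size)

    def subset(self, idx: np.ndarray) -> "DailyGranule":
        return DailyGranule(
            self.sensor, self.year, self.doy,
            self.lon_lo[idx], self.lon_hi[idx], self.lat_lo[idx], self.lat_hi[idx],
            self.column[idx], self.cloud_frac[idx], self.snow[idx],
            self.kernel[idx], self.apriori[idx],
        )


def _tile_edges(lo: float, hi: float, size: float, offset: float) -> np.ndarray:
    """Left edges of tiles of ``size`` covering [lo, hi), shifted by offset."""
    start = lo + offset - size
    n = int(math.ceil((hi - start) / size))
    edges = start + size * np.arange(n)
    return edges[(edges + size > lo + 1e-9) & (edges < hi - 1e-9)]


def sensor_offset_counts(grid: GridSpec, sensor: SensorSpec) -> tuple[int, int]:
    """Number of distinct lon/lat placement offsets of a sensor's layout."""
    if sensor.sampling == "overlap":
        sx = sensor.stride_lon or sensor.footprint_lon
        sy = sensor.stride_lat or sensor.footprint_lat
    else:
        sx, sy = sensor.footprint_lon, sensor.footprint_lat
    return max(round(sx / grid.dlon), 1), max(round(sy / grid.dlat), 1)


def footprint_layout(
    grid: GridSpec, sensor: SensorSpec, phase: int, offx: float, offy: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Footprint rectangles for one band phase and placement offset,
    clipped to the grid extent.

    The sensor observes one longitude band of width extent/revisit per
    band phase, cycling so every cell is covered once per revisit period.
    """
    ext_lon = grid.nlon * grid.dlon
    band_w = ext_lon / sensor.revisit
    b0 = grid.lon0 + (phase % sensor.revisit) * band_w
    b1 = b0 + band_w

    if sensor.sampling == "overlap":
        sx = sensor.stride_lon or sensor.footprint_lon
        sy = sensor.stride_lat or sensor.footprint_lat
        cx = b0 + offx + sx * (np.arange(int(round(band_w / sx))) + 0.5) - sx / 2
        cy = (
            grid.lat0 + offy
            + sy * (np.arange(int(round(grid.nlat * grid.dlat / sy))) + 0.5) - sy / 2
        )
        lon_lo = cx - sensor.footprint_lon / 2
        lon_hi = cx + sensor.footprint_lon / 2
        lat_lo = cy - sensor.footprint_lat / 2
        lat_hi = cy + sensor.footprint_lat / 2
    else:
        ex = _tile_edges(b0, b1, sensor.footprint_lon, offx)
        ey = _tile_edges(grid.lat0, grid.lat1, sensor.footprint_lat, offy)
        lon_lo, lon_hi = ex, ex + sensor.footprint_lon
        lat_lo, lat_hi = ey, ey + sensor.footprint_lat

    LO, LA = np.meshgrid(np.arange(lon_lo.size), np.arange(lat_lo.size), indexing="ij")
    lon_lo = np.clip(lon_lo[LO.ravel()], grid.lon0, grid.lon1)
    lon_hi = np.clip(lon_hi[LO.ravel()], grid.lon0, grid.lon1)
    lat_lo_f = np.clip(lat_lo[LA.ravel()], grid.lat0, grid.lat1)
    lat_hi_f = np.clip(lat_hi[LA.ravel()], grid.lat0, grid.lat1)
    keep = (lon_hi - lon_lo > 0.5 * grid.dlon) & (lat_hi_f - lat_lo_f > 0.5 * grid.dlat)
    return lon_lo[keep], lon_hi[keep], lat_lo_f[keep], lat_hi_f[keep]


def _footprint_rects(
    grid: GridSpec, sensor: SensorSpec, day_index: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Footprint rectangles for one day.

    Overlap-mode sensors cycle deterministically through every offset
    combination, so their long-term smearing kernel is reproducible by
    enumerating the same combinations (observation_model.sensor_smooth);
    tile-mode sensors draw a random placement offset each day.
    """
    phase = day_index % sensor.revisit
    nx, ny = sensor_offset_counts(grid, sensor)
    if sensor.sampling == "overlap":
        offx = ((day_index // sensor.revisit) % nx) * grid.dlon
        offy = ((day_index // (sensor.revisit * nx)) % ny) * grid.dlat
    else:
        offx = rng.integers(nx) * grid.dlon
        offy = rng.integers(ny) * grid.dlat
    return footprint_layout(grid, sensor, phase, offx, offy)


def _cloud_mean(cloud: CloudConfig, doy: int, peak_doy: int) -> float:
    w = 0.5 * (1.0 + math.cos(2 * math.pi * (doy - peak_doy) / DAYS_PER_YEAR))
    return cloud.mean_summer + (cloud.mean_winter - cloud.mean_summer) * w


def simulate_granules(
    truth: TruthScenario,
    ctm: CtmSurrogate,
    sensor: SensorSpec,
    years: Iterable[int],
    cloud: CloudConfig | None = None,
    snow: SnowConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Iterator[DailyGranule]:
    """Yield one granule per scenario day for each requested year.

    Each footprint's column is the area-weighted mean of the true fine
    column over its rectangle, multiplied by the averaging-kernel
    distortion of the retrieval a priori, the sensor's calibration bias,
    and truncated multiplicative Gaussian noise.
    """
    cfg = truth.config
    cloud = cloud or cfg.cloud
    if rng is None:
        rng = np.random.default_rng(truth._sensor_seeds[sensor.name])
    kern = sensor.kernel(cfg.n_layers)
    dist_fine = block_repeat(ctm.distortion(kern), ctm.flat, ctm.flon)
    grid = truth.grid
    years = list(years)
    for year in years:
        if not (sensor.era[0] <= year <= sensor.era[1]):
            raise ValueError(
                f"year {year} outside {sensor.name} era {sensor.era[0]}-{sensor.era[1]}"
            )
    ndays = cfg.doys.size
    for year in years:
        snow_lat = truth.snow_flags(year)  # (ndays, nlat)
        for di, doy in enumerate(cfg.doys):
            day_index = (year - cfg.years[0]) * ndays + di
            lon_lo, lon_hi, lat_lo, lat_hi = _footprint_rects(grid, sensor, day_index, rng)
            olat, olon = overlap_matrices(grid, lon_lo, lon_hi, lat_lo, lat_hi)
            col_true = footprint_means(grid, ctm.fine_column_truth(year, int(doy)), olat, olon)
            # distortion / a-priori taken at the footprint centre cell
            ci, cj = _center_cells(grid, lon_lo, lon_hi, lat_lo, lat_hi)
            factor = dist_fine[ci, cj]
            if sensor.noise_sd > 0:
                noise = np.maximum(1.0 + sensor.noise_sd * rng.standard_normal(col_true.size), 0.1)
            else:
                noise = 1.0
            column = col_true * factor * sensor.bias * noise
            m = _cloud_mean(cloud, int(doy), cfg.seasonal_peak_doy)
            if m <= 0.0:
                cf = np.zeros(col_true.size)
            elif m >= 1.0:
                cf = np.ones(col_true.size)
            else:
                cf = rng.beta(m * cloud.concentration, (1 - m) * cloud.concentration,
                              col_true.size)
            snow_flag = snow_lat[di][ci]
            cell_frac = ctm.fractions[ci // ctm.flat, cj // ctm.flon]
            yield DailyGranule(
                sensor.name, year, int(doy),
                lon_lo, lon_hi, lat_lo, lat_hi,
                column, cf, snow_flag,
                np.broadcast_to(kern, (col_true.size, kern.size)).copy(),
                cell_frac.copy(),
            )


def _center_cells(grid, lon_lo, lon_hi, lat_lo, lat_hi):
    ci = np.clip(
        ((0.5 * (lat_lo + lat_hi) - grid.lat0) / grid.dlat).astype(int), 0, grid.nlat - 1
    )
    cj = np.clip(
        ((0.5 * (lon_lo + lon_hi) - grid.lon0) / grid.dlon).astype(int), 0, grid.nlon - 1
    )
    return ci, cj


# ----------------------------------------------------------------------
# population
# ----------------------------------------------------------------------
@dataclass
class PopulationSeries:
    """Per-cell population counts at 5-year snapshots on the analysis grid.

    Counts were generated on a ``fine_factor``-times finer grid and
    aggregated by summation, so totals are conserved exactly.
    """

    grid: GridSpec
    years: tuple[int, ...]
    counts: dict[int, np.ndarray]
    native_note: str = "generated finer, aggregated by summation"

    def total(self, year: int) -> float:
        return float(self.counts[year].sum())


def make_population(config: ScenarioConfig, truth: TruthScenario | None = None) -> PopulationSeries:
    """Population concentrated log-normally around the urban hotspots."""
    truth = truth or make_truth_scenario(config)
    pc = config.population
    g = config.grid
    f = pc.fine_factor
    fine = GridSpec(g.lat0, g.lon0, g.nlat * f, g.nlon * f, g.dlat / f, g.dlon / f)
    latc, lonc = np.meshgrid(fine.lat_centers, fine.lon_centers, indexing="ij")
    urban = np.zeros(fine.shape)
    total_peak = sum(h.peak for h in config.hotspots) or 1.0
    for h in config.hotspots:
        d2 = (latc - h.lat) ** 2 + (lonc - h.lon) ** 2
        urban += (h.peak / total_peak) * np.exp(-d2 / (2.0 * pc.urban_sigma**2))
    if urban.sum() > 0:
        urban *= pc.urban_fraction / urban.sum()
    rural = np.full(fine.shape, (1.0 - pc.urban_fraction) / fine.nlat / fine.nlon)
    density = urban + rural
    if pc.texture_sd > 0:
        density = density * np.exp(
            pc.texture_sd * truth.rng_population.standard_normal(fine.shape)
        )
    density *= pc.total / density.sum()

    region_fine = np.repeat(np.repeat(truth.regions.ids, f, axis=0), f, axis=1)
    y0 = pc.snapshot_years[0]
    counts = {}
    for y in pc.snapshot_years:
        growth = np.ones(fine.shape)
        for rid in truth.regions.region_ids():
            gpct = pc.growth_pct.get(rid, 0.0)
            growth[region_fine == rid] = (1.0 + gpct / 100.0) ** (y - y0)
        fine_counts = density * growth
        counts[y] = fine_counts.reshape(g.nlat, f, g.nlon, f).sum(axis=(1, 3))
    return PopulationSeries(g, tuple(pc.snapshot_years), counts)


# ----------------------------------------------------------------------
# stations
# ----------------------------------------------------------------------
@dataclass
class StationRecord:
    """A ground monitor: daily midmorning NO2 sampled from the truth cell,
    scaled by a multiplicative local bias factor."""

    lat: float
    lon: float
    site_class: str
    bias: float
    years: tuple[int, ...]
    doys: np.ndarray
    values: np.ndarray  # (nyears, ndays)

    def __post_init__(self) -> None:
        if self.bias <= 0:
            raise ValueError("station bias factor must be positive")


_CLASS_BIAS = {"rural": 0.9, "suburban": 1.0, "urban": 1.15, "traffic": 1.6}


def make_stations(
    truth: TruthScenario,
    n: int | None = None,
    classes: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> list[StationRecord]:
    """Sample station records from the truth.

    Stations sit preferentially near hotspots (urban/traffic closest),
    carry a lognormal local bias times a class factor, and report the
    truth at their grid cell each scenario day.
    """
    cfg = truth.config
    if n is None:
        n = cfg.stations.n
    if n <= 0:
        raise ValueError("station count must be positive")
    rng = rng or truth.rng_stations
    if classes is None:
        names = list(cfg.stations.class_probs)
        probs = np.array([cfg.stations.class_probs[c] for c in names], dtype=float)
        probs /= probs.sum()
        classes = rng.choice(names, size=n, p=probs)
    g = truth.grid
    spots = cfg.hotspots
    weights = np.array([h.peak for h in spots], dtype=float)
    weights = weights / weights.sum() if weights.sum() > 0 else None
    out: list[StationRecord] = []
    eps = 1e-6
    for cls in classes:
        if spots and cls != "rural":
            h = spots[rng.choice(len(spots), p=weights)]
            sigma = {"traffic": 0.05, "urban": 0.15, "suburban": 0.5}[cls]
            lat = h.lat + sigma * rng.standard_normal()
            lon = h.lon + sigma * rng.standard_normal()
        else:
            lat = g.lat0 + rng.uniform(0, g.nlat * g.dlat)
            lon = g.lon0 + rng.uniform(0, g.nlon * g.dlon)
        lat = float(np.clip(lat, g.lat0 + eps, g.lat1 - eps))
        lon = float(np.clip(lon, g.lon0 + eps, g.lon1 - eps))
        bias = _CLASS_BIAS[cls] * float(np.exp(cfg.stations.bias_sd * rng.standard_normal()))
        i, j = g.locate(lat, lon)
        values = truth.cell_series(i, j) * bias
        out.append(
            StationRecord(lat, lon, str(cls), bias, tuple(cfg.year_list), cfg.doys.copy(), values)
        )
    return out
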