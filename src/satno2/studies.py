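"""Prepackaged synthetic experiments: parameter recovery, sampling-bias
correction, downscaling skill and record continuity.

These are the package's own validation studies; the test suite and the
acceptance script both run them, at the study conditions defined by the
scenario defaults (see the methods note for sizes and rationale).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .exposure_metrics import interpolate_population, pwm
from .harmonization import boxcar_smooth, overlap_correlation, ratio_downscale
from .pipeline import PipelineConfig, run_pipeline, smoothed_reference_field
from .synthetic_world import ScenarioConfig

__all__ = [
    "recovery_study",
    "sampling_correction_study",
    "downscaling_study",
    "highlat_scenario",
]

log = logging.getLogger(__name__)


def recovery_study(n_seeds: int = 50, base_seed: int = 0,
                   cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Regional relative-trend recovery across seeded replicate worlds.

    For each seed the full pipeline runs on a fresh synthetic world and
    each region's estimated PWM relative trend (with its 95% CI) is
    compared against the truth trend — the same OLS estimator applied to
    the deterministic (noise- and anomaly-free) truth PWM series.
    Returns one row per (seed, region) with coverage and error columns.
    """
    rows = []
    for k in range(n_seeds):
        seed = base_seed + k
        base_cfg = cfg or PipelineConfig()
        scenario = dataclasses.replace(base_cfg.scenario, seed=seed)
        run_cfg = dataclasses.replace(base_cfg, scenario=scenario,
                                      compare_stations=False)
        result = run_pipeline(run_cfg)
        est = result.trends_frame.query("period == 'full' and region_id != 0")
        tru = result.truth_trends.set_index("region_id")["rel_trend_pct"]
        for _, row in est.iterrows():
            rid = int(row["region_id"])
            truth_val = float(tru[rid])
            rows.append({
                "seed": seed,
                "region_id": rid,
                "est_rel_trend": row["rel_trend_pct"],
                "ci_lo": row["rel_ci_lo"],
                "ci_hi": row["rel_ci_hi"],
                "truth_rel_trend": truth_val,
                "covered": bool(row["rel_ci_lo"] <= truth_val <= row["rel_ci_hi"]),
                "error": row["rel_trend_pct"] - truth_val,
            })
        log.info("recovery seed %d done", seed)
    return pd.DataFrame(rows)


def recovery_summary(df: pd.DataFrame) -> dict:
    bias = df.groupby("region_id")["error"].mean()
    return {
        "coverage": float(df["covered"].mean()),
        "mean_abs_bias": float(bias.abs().mean()),
        "per_region_coverage": df.groupby("region_id")["covered"].mean().to_dict(),
        "per_region_bias": bias.to_dict(),
    }


def highlat_scenario(seed: int = 0) -> ScenarioConfig:
    """A high-latitude window with seasonal snow: winters are lost to the
    snow filter (and heavier cloud), making the sampling-bias correction
    load-bearing."""
    cfg = ScenarioConfig(seed=seed)
    return dataclasses.replace(
        cfg,
        lat0=50.0,
        hotspots=[dataclasses.replace(h, lat=h.lat + 18.0) for h in cfg.hotspots],
        snow=dataclasses.replace(cfg.snow, lat_threshold=45.0),
    )


def sampling_correction_study(seed: int = 0) -> dict:
    """Effect and skill of the sampling-bias correction under
    winter-deficient sampling.

    Runs the high-latitude scenario twice (correction on / off) and
    reports the long-term global PWM under both, plus the mean absolute
    error of the annual mean surface fields against the truth annual
    means over cells valid in both runs.
    """
    out = {}
    for correct in (True, False):
        cfg = PipelineConfig(scenario=highlat_scenario(seed),
                             correct_sampling=correct, compare_stations=False)
        result = run_pipeline(cfg)
        key = "corrected" if correct else "uncorrected"
        out[key] = result
    res_c, res_u = out["corrected"], out["uncorrected"]
    truth = res_c.truth
    years = res_c.surface.years
    pop = res_c.population

    pwm_c = [pwm(res_c.surface.surface[k], interpolate_population(pop, y),
                 res_c.regions, None) for k, y in enumerate(years)]
    pwm_u = [pwm(res_u.surface.surface[k], interpolate_population(pop, y),
                 res_u.regions, None) for k, y in enumerate(years)]

    err_c, err_u = [], []
    for k, y in enumerate(years):
        t = truth.annual_mean_surface(y).values
        both = ~np.isnan(res_c.surface.surface[k]) & ~np.isnan(res_u.surface.surface[k])
        err_c.append(np.abs(res_c.surface.surface[k][both] - t[both]))
        err_u.append(np.abs(res_u.surface.surface[k][both] - t[both]))
    return {
        "pwm_corrected": float(np.mean(pwm_c)),
        "pwm_uncorrected": float(np.mean(pwm_u)),
        "mae_corrected": float(np.concatenate(err_c).mean()),
        "mae_uncorrected": float(np.concatenate(err_u).mean()),
        "trend_corrected": res_c.trends_frame,
        "trend_uncorrected": res_u.trends_frame,
    }


def downscaling_study(seed: int = 0, year: int = 1999) -> dict:
    """Does ratio downscaling add fine-scale skill to the coarse sensor?

    Compares the spatial correlation (over all cells) of (a) the raw
    coarse-sensor annual mean and (b) its ratio-downscaled version with
    the true fine-scale annual column for one coarse-era year.
    """
    cfg = PipelineConfig(scenario=ScenarioConfig(seed=seed), compare_stations=False)
    result = run_pipeline(cfg)
    truth, ctm = result.truth, result.ctm
    grid = truth.grid
    true_col = truth.annual_mean_surface(year).values / ctm.fine_ratio()

    coarse = result.annuals["gome"][year]
    ref_years = range(cfg.ref_downscale[0], cfg.ref_downscale[1] + 1)
    fine_ref = np.nanmean(np.stack([result.annuals[cfg.reference_sensor][y]
                                    for y in ref_years]), axis=0)
    smoothed_ref = smoothed_reference_field(cfg, truth, result.annuals)
    if smoothed_ref is None:
        smoothed_ref = boxcar_smooth(fine_ref, *cfg.boxcar_window, grid=grid)
    downscaled = ratio_downscale(coarse, fine_ref, smoothed_ref)
    return {
        "r_coarse": overlap_correlation(coarse, true_col),
        "r_downscaled": overlap_correlation(downscaled, true_col),
        "continuity_frac": result.continuity_frac,
        "result": result,
    }
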