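import dataclasses

import numpy as np
import pytest

from satno2.pipeline import PipelineConfig, run_pipeline
from satno2.synthetic_world import CloudConfig, ScenarioConfig


def flat_world_config(seed: int = 0, gome2_bias: float = 1.1) -> PipelineConfig:
    """Flat, noise-free, cloud-free, trend-free world: the end-to-end
    identity case (every stage should be exactly invertible)."""
    sc = ScenarioConfig(
        background=1.0,
        hotspots=[],
        region_trends={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0},
        seasonal_amplitude=0.0,
        interannual_sd=0.0,
        ratio_variation=0.0,
        cloud=CloudConfig(0.0, 0.0, 4.0),
        seed=seed,
    )
    sc = dataclasses.replace(
        sc,
        sensors=[
            dataclasses.replace(s, noise_sd=0.0,
                                bias=gome2_bias if s.name == "gome2" else 1.0)
            for s in sc.sensors
        ],
    )
    return PipelineConfig(scenario=sc, compare_stations=False)


@pytest.fixture(scope="session")
def default_result():
    """One full pipeline run at the default study conditions."""
    return run_pipeline(PipelineConfig(compare_stations=False))


@pytest.fixture(scope="session")
def flat_result():
    return run_pipeline(flat_world_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
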