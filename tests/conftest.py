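import dataclasses
import math
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from betamorph import PipelineParams, SimConfig


@pytest.fixture(scope="session")
def clean_config() -> SimConfig:
    """Small artifact-free section: fast, perfect-recovery conditions."""
    return SimConfig(
        image_height_px=256,
        image_width_px=256,
        pixel_size_mm=0.002,
        islet_count_mean=3.0,
        islet_radius_log_mean=math.log(0.010),
        min_islet_gap_mm=0.030,
        speckle_density=0.0,
        dim_islet_fraction=0.0,
        bleach_gradient_strength=0.0,
        adipose_region_count=0,
        lymph_node_count=0,
    )


@pytest.fixture(scope="session")
def artifact_config(clean_config) -> SimConfig:
    """Small artifact-rich section (speckles, dim islets, confounders)."""
    return dataclasses.replace(
        clean_config,
        speckle_density=150.0,
        dim_islet_fraction=0.4,
        bleach_gradient_strength=0.15,
        adipose_region_count=1,
        lymph_node_count=1,
    )


@pytest.fixture(scope="session")
def default_params() -> PipelineParams:
    return PipelineParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(20180206)
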