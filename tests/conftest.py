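import numpy as np
import pytest

from paleoshift.dispersal import discretize_kernel
from paleoshift.synthetic_world import (
    ClimateTrajectory,
    LandscapeConfig,
    VirtualSpecies,
    gen_climate_series,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_landscape():
    return LandscapeConfig(n_rows=8, n_cols=10, fine_per_coarse=2, seed=7)


@pytest.fixture
def short_trajectory():
    # three cold slices, a transition, then stability
    return ClimateTrajectory(start_bp=12_000, end_bp=10_250, noise_sd=0.3)


@pytest.fixture
def tiny_climate(tiny_landscape, short_trajectory):
    return gen_climate_series(tiny_landscape, short_trajectory)


@pytest.fixture
def oak():
    return VirtualSpecies(name="oak_like")


@pytest.fixture
def small_kernel():
    return discretize_kernel("exponential-power", {"a": 600.0, "c": 1.0},
                             cell_size_m=500.0, ld_probability=0.0)
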