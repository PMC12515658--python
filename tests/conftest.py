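import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gliosim as g

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scenario_set():
    return g.default_scenarios()


@pytest.fixture(scope="session")
def row1(scenario_set):
    return scenario_set[1]


@pytest.fixture(scope="session")
def grid32():
    return g.make_brain_grid((32, 32, 8))


@pytest.fixture(scope="session")
def baseline32(grid32, row1):
    """Noise-free baseline phantom study shaped by scenario 1's windows."""
    spec = g.PhantomSpec(dims=(32, 32, 8), noise_sd=0.0)
    return g.make_baseline_study(grid32, spec, row1)


@pytest.fixture(scope="session")
def uniform_white_grid():
    """Small all-white-matter domain: uniform fields stay uniform on it."""
    labels = np.full((8, 8, 8), int(g.TissueLabel.WHITE), np.uint8)
    return g.VoxelGrid(labels, (0.9, 0.9, 7.0))
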