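import numpy as np
import pytest

from ramanlcf import (
    WavenumberGrid,
    build_basis,
    component_library,
    default_scenario,
    generate_scenario_series,
)


@pytest.fixture(scope="session")
def library():
    return component_library()


@pytest.fixture(scope="session")
def grid():
    return WavenumberGrid.default()


@pytest.fixture(scope="session")
def basis(library, grid):
    return build_basis(library, grid)


@pytest.fixture(scope="session")
def noiseless_series():
    """Default 12-hour scenario with noise and decay switched off."""
    scenario = default_scenario(seed=0, sigma=0.0, decay_rate=0.0)
    return generate_scenario_series(scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
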