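import numpy as np
import pytest

from rstarsim import SimulationConfig, build_parameter_space


@pytest.fixture(scope="session")
def low_growth_points():
    return build_parameter_space("low_growth")


@pytest.fixture(scope="session")
def high_growth_points():
    return build_parameter_space("high_growth")


@pytest.fixture()
def rng():
    return np.random.default_rng(20150812)


@pytest.fixture()
def tiny_config():
    """Desk-scale sweep config: 3 points, 2 sizes, 2 reps, short horizon."""
    return SimulationConfig(
        regime_label="low_growth",
        n_points=3,
        initial_sizes=(1, 512),
        n_replicates=2,
        horizon=200,
        base_seed=42,
    )
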