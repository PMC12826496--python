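import numpy as np
import pytest

from exotaxis import ScenarioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A short, light scenario for engine-level unit tests."""
    return ScenarioConfig(
        mean_cargo=25.0,
        hill=3.0,
        total_time=120.0,
        dt_cell=40.0,
        dt_exo=0.1,
        n_runs=4,
        base_seed=11,
    )
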