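import numpy as np
import pytest

from chemodetect import ScenarioConfig, simulate


@pytest.fixture(scope="session")
def scenario_table():
    """Session-cached simulator output factory (simulations are reused
    across test modules to keep the suite fast)."""
    cache: dict = {}

    def get(scenario: str, seed: int = 11, **kwargs):
        key = (scenario, seed, tuple(sorted(kwargs.items())))
        if key not in cache:
            cache[key] = simulate(
                ScenarioConfig(scenario=scenario, seed=seed, **kwargs))
        return cache[key]

    return get


@pytest.fixture
def rng():
    return np.random.default_rng(20210722)
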