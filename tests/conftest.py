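import numpy as np
import pytest

import herbchron as hc


@pytest.fixture(scope="session")
def small_config():
    """A compact synthetic study: fewer plants, same structure."""
    return hc.SyntheticConfig(seed=20170801, n_plants=40)


@pytest.fixture(scope="session")
def small_climate(small_config):
    return hc.simulate_daily_climate(small_config)


@pytest.fixture(scope="session")
def small_rings(small_config, small_climate):
    rings, truth = hc.simulate_ring_set(small_config, small_climate)
    return rings, truth


def make_series(plant_id="P1", last_year=2017, widths=(30.0, 25.0, 22.0, 21.0, 20.0)):
    return hc.RingSeries(plant_id, last_year, tuple(widths))
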