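import numpy as np
import pytest

from cfsekinetics import (DivisionTimeModel, InitialIntensityModel,
                          MixtureParams, log_bin_edges)
from cfsekinetics.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def default_params():
    return MixtureParams(bulk=DivisionTimeModel(15.0, 2.0, 4.0),
                         slow=DivisionTimeModel(60.0, 2.0, 6.0),
                         slow_fraction=0.015)


@pytest.fixture(scope="session")
def init_model():
    return InitialIntensityModel("lognormal", log_mean=np.log(1e4), log_sd=0.4)


@pytest.fixture(scope="session")
def bin_edges():
    # floor at 1% of the day-0 median, ceiling near its 99.9th percentile
    return log_bin_edges(100.0, 1e4 * np.exp(3.1 * 0.4), 256)


@pytest.fixture(scope="session")
def small_experiment(default_params):
    """20k-lineage noisy two-population experiment shared across tests."""
    cfg = SimulationConfig(seed=42, n_cells=20_000, params=default_params)
    return cfg, simulate_experiment(cfg)
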