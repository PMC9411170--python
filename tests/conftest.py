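import numpy as np
import pytest

from nirsnet.datatypes import ROITimeSeries
from nirsnet.synthetic import (
    GroundTruthNetwork,
    default_network,
    simulate_var_network,
    unidirectional_pair,
)


@pytest.fixture(scope="session")
def bivariate_var():
    """The reference bivariate VAR(1): x drives y with lag-1 weight 0.5,
    self-memory 0.5, unit innovations (nominal 1 Hz grid)."""
    A = np.zeros((2, 2, 1))
    A[0, 0, 0] = A[1, 1, 0] = 0.5
    A[1, 0, 0] = 0.5
    return A, np.eye(2)


@pytest.fixture(scope="session")
def pair_network():
    return unidirectional_pair()


@pytest.fixture(scope="session")
def null_pair():
    """Two independent regions (zero cross-coupling)."""
    return GroundTruthNetwork(("X", "Y"), np.dstack([np.diag([0.6, 0.6])]), np.eye(2))


@pytest.fixture(scope="session")
def five_roi_network():
    return default_network()


@pytest.fixture(scope="session")
def roi_series_300s(five_roi_network):
    return simulate_var_network(five_roi_network, int(300 * 25), 25.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_series(values, fs=25.0, labels=None):
    values = np.asarray(values, float)
    if labels is None:
        labels = tuple(f"R{i}" for i in range(values.shape[1]))
    return ROITimeSeries(fs, values, labels)
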