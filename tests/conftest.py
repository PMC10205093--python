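import numpy as np
import pytest

from spikecode.behavior import simulate_trajectory


@pytest.fixture(scope="session")
def traj_60s():
    """One minute of W-track behavior on the 10 ms grid (6000 bins)."""
    return simulate_trajectory(60.0, seed=101)


@pytest.fixture(scope="session")
def traj_10min():
    """Ten minutes of behavior (60000 bins) for statistical checks."""
    return simulate_trajectory(600.0, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
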