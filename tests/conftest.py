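import numpy as np
import pytest

import herdmark as hm


@pytest.fixture(scope="session")
def prior_matrix() -> hm.TransitionMatrix:
    """Packaged prior nine-state matrix, rows renormalized."""
    return hm.load_prior_transition_matrix()


@pytest.fixture(scope="session")
def prior_pi() -> hm.StationaryDistribution:
    """Packaged reference stationary distribution, normalized."""
    return hm.load_prior_stationary_distribution()


@pytest.fixture(scope="session")
def prior_pi_printed() -> np.ndarray:
    """The reference stationary vector exactly as shipped (sums to 0.997)."""
    return hm.load_prior_stationary()["pi"].to_numpy(dtype=float)


@pytest.fixture(scope="session")
def sample_table() -> hm.ActivityTable:
    return hm.load_sample_activity_table()


@pytest.fixture(scope="session")
def error_table():
    return hm.load_simulation_error_table()


@pytest.fixture(scope="session")
def two_state_space() -> hm.StateSpace:
    return hm.StateSpace(("A", "B"))


@pytest.fixture(scope="session")
def flip_chain(two_state_space) -> hm.TransitionMatrix:
    """The period-2 chain that alternates deterministically."""
    return hm.TransitionMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]),
                               states=two_state_space)
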