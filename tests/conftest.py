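import numpy as np
import pytest

import ribofret as rf


@pytest.fixture(scope="session")
def small_selection():
    """A small ctrl-phe dataset shared by read-only tests."""
    traceset, ground_truth = rf.simulate_dataset("ctrl-phe", 60, seed=101)
    return traceset, ground_truth


@pytest.fixture(scope="session")
def small_pretrans():
    """A small pretrans-low dataset shared by read-only tests."""
    traceset, ground_truth = rf.simulate_dataset("pretrans-low", 80, seed=202)
    return traceset, ground_truth


@pytest.fixture
def two_state_scheme():
    """Symmetric two-state exchanger, stationary distribution (1/2, 1/2)."""
    return rf.KineticScheme(
        state_names=("low", "high"),
        fret_mean=np.array([0.2, 0.7]),
        fret_sd=np.array([0.05, 0.05]),
        rate_matrix=np.array([[0.0, 3.0], [3.0, 0.0]]),
        initial_distribution=np.array([0.5, 0.5]),
    )
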