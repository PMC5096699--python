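import numpy as np
import pandas as pd
import pytest

from popfactor import (
    PresenceDesign,
    TrialTensor,
    generate_trials,
    make_block_patterns,
)


@pytest.fixture
def tiny_tensor():
    """2 trials x 2 bins x 2 neurons with known counts."""
    counts = np.array([[[1, 2], [3, 4]], [[0, 1], [0, 5]]])
    return TrialTensor(
        counts=counts,
        bin_width=10.0,
        window=(0.0, 20.0),
        labels=np.array(["a", "b"]),
    )


@pytest.fixture
def event_table():
    return pd.DataFrame(
        {
            "trial": [0, 0, 0, 1, 1],
            "stimulus": ["a", "a", "a", "b", "b"],
            "neuron": [0, 1, 1, 0, 1],
            "time_ms": [15.0, 4.0, 295.0, 310.0, 0.0],
        }
    )


@pytest.fixture(scope="session")
def separable_patterns():
    return make_block_patterns("separable")


@pytest.fixture(scope="session")
def small_mixture_tensor(separable_patterns):
    """A modest high-SNR mixture dataset shared across decomposition tests."""
    return generate_trials(
        separable_patterns, PresenceDesign.mixture(0.5), 120, seed=11
    )
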