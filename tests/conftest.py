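import numpy as np
import pytest

import qfnirs as qf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixtures():
    return qf.toy_fixtures()


@pytest.fixture(scope="session")
def micro_trials(fixtures):
    """2 subjects x 4 balanced trials, 27 channels, 30 s at 10 Hz."""
    return fixtures["micro_dataset"]


@pytest.fixture(scope="session")
def micro_windows(micro_trials):
    return qf.make_windows(qf.extract_analysis_window(micro_trials))


@pytest.fixture(scope="session")
def full_trials():
    """Default stated-world dataset: 14 subjects x 10 trials."""
    return qf.simulate_dataset(qf.SynthConfig(seed=3))
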