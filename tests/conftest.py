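import numpy as np
import pytest

import convtrace as ct


@pytest.fixture(scope="session")
def default_truth():
    """One simulated quartet under the default two-conversion preset."""
    return ct.simulate_duplicate_loci(ct.default_config(seed=11))


@pytest.fixture(scope="session")
def default_track(default_truth):
    return default_truth.track()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
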