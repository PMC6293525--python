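import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ccqg

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_founders():
    """Two 50-cM chromosomes with 40 markers each."""
    return ccqg.simulate_founders([40, 40], [50.0, 50.0], seed=101)


@pytest.fixture(scope="session")
def small_panel(small_founders):
    """15 CC lines with true mosaics, noiseless truth probabilities."""
    mosaics = ccqg.breed_cc_panel(small_founders, 15, seed=102)
    truth = ccqg.descent_from_truth(mosaics, small_founders.gmap)
    return mosaics, truth
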