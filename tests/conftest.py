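import numpy as np
import pytest

from pupilcar import MxaConfig, SimConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


#: short recordings keep the cohort fixtures fast; the Mxa config used with
#: them must lower min_duration_s accordingly
SHORT = dict(duration_s=120.0)


@pytest.fixture(scope="session")
def short_mxa_config():
    return MxaConfig(min_duration_s=100.0)


@pytest.fixture(scope="session")
def small_cohort():
    """18-patient synthetic cohort with 2-min recordings."""
    config = SimConfig(n_septic=10, n_nonseptic=8, seed=42, **SHORT)
    records, truth = generate_cohort(config)
    return records, truth
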