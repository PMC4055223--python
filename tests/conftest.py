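import numpy as np
import pytest

from paqcal import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """Twelve noise-free-schedule participants used by round-trip tests."""
    params = synthetic.CohortParams(n_participants=12, seed=3, pct_mvpa_day_sd=0.0)
    return synthetic.generate_cohort(params)


@pytest.fixture
def rng():
    return np.random.default_rng(20140516)
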