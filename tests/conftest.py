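import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20160428)


@pytest.fixture(scope="session")
def urn_cohort():
    """A small averse cohort shared by stats/io tests."""
    from ambival import simulate_cohort

    return simulate_cohort(
        n_subjects=4, task="urn", n_trials=300, model="fe",
        alpha_range=(10.0, 25.0), beta_range=(-4.0, -2.0), seed=11,
    )
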