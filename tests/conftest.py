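import numpy as np
import pytest

import breathdisc as bd


@pytest.fixture(scope="session")
def default_trace():
    return bd.simulate_maneuver()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but analysable cohort (90 COPD / 30 cancer, 8 incident)."""
    spec = bd.CohortSpec(n_copd=90, n_cancer=30, n_incident=8, seed=11)
    recordings, metadata = bd.generate_cohort(spec)
    return spec, recordings, metadata


@pytest.fixture(scope="session")
def small_features(small_cohort):
    _, recordings, metadata = small_cohort
    return bd.extract_cohort(recordings), metadata


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
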