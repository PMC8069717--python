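import numpy as np
import pytest

from eegfatigue import (
    SyntheticCohortConfig,
    extract_features,
    generate_cohort,
    segment_all,
)

#: compact cohort for pipeline-level unit tests: 2 subjects, 8 channels,
#: 30 s per state — same structure as the default cohort, much cheaper
SMALL_COHORT = SyntheticCohortConfig(
    n_subjects=2,
    n_channels=8,
    duration_per_state=30.0,
    informative_channels=(0, 1, 2),
    seed=123,
)


@pytest.fixture(scope="session")
def small_cohort():
    recordings, truth = generate_cohort(SMALL_COHORT)
    return recordings, truth


@pytest.fixture(scope="session")
def small_features(small_cohort):
    recordings, truth = small_cohort
    X = extract_features(segment_all(recordings))
    return X, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
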