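import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import riftpipe as rp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_truth() -> rp.GroundTruth:
    """A fast, fully featured generator configuration for unit tests."""
    return rp.GroundTruth(
        n_subjects=2,
        n_trials_per_condition=8,
        n_channels=6,
        n_tagged_channels=2,
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_dataset(small_truth) -> rp.Dataset:
    return rp.simulate_dataset(small_truth)


@pytest.fixture(scope="session")
def small_events(small_dataset):
    return rp.events_to_frame(small_dataset.events)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(99)
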