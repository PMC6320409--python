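import numpy as np
import pytest

from transferkit.pipelines import filter_recordings
from transferkit.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down session: 3 subjects, 6 minutes, 3 transfers each."""
    return SimulationConfig(
        n_subjects=3, session_minutes=6.0, transfers_per_subject=3, seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_filtered(small_dataset):
    return filter_recordings(small_dataset.recordings)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
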