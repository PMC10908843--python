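import numpy as np
import pytest

from sclshape.features import feature_table
from sclshape.preprocess import preprocess_cohort
from sclshape.simulate import SimConfig, simulate_session


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced cohort for fast unit tests: 8 people, 3 scenes, short windows."""
    return SimConfig(n_participants=8, tier4_fraction=0.25, n_scenes=3,
                     guided_dur=20.0, self_dur=30.0, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_session(small_config)


@pytest.fixture(scope="session")
def small_segments(small_cohort):
    recordings, _ = small_cohort
    segments, notes = preprocess_cohort(recordings)
    assert not notes
    return segments


@pytest.fixture(scope="session")
def small_features(small_config, small_segments):
    return feature_table(small_segments, fs=small_config.fs,
                         scenes=small_config.scenes)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort (30 persons, six analysis scenes) at 40 Hz."""
    cfg = SimConfig(n_scenes=6, seed=5)
    recordings, truth = simulate_session(cfg)
    return cfg, recordings, truth


@pytest.fixture(scope="session")
def default_segments(default_cohort):
    _, recordings, _ = default_cohort
    segments, _ = preprocess_cohort(recordings)
    return segments


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
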