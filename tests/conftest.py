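import numpy as np
import pytest

from eitgest import SimConfig, build_schedule, simulate_dataset


@pytest.fixture(scope="session")
def schedule16():
    return build_schedule(16)


@pytest.fixture(scope="session")
def small_sim():
    """Cheap dataset: 2 sessions x 3 iterations x 12 gestures x 3 frames."""
    cfg = SimConfig(sessions_per_subject=2, iterations_per_session=3,
                    frames_per_gesture=3, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_ds(small_sim):
    return small_sim[0]


@pytest.fixture(scope="session")
def multi_subject_sim():
    cfg = SimConfig(n_subjects=3, sessions_per_subject=2, iterations_per_session=2,
                    frames_per_gesture=3, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noise_free_offsets_sim():
    """Additive session offsets only: no gain, rotation, drift, or noise."""
    cfg = SimConfig(sessions_per_subject=4, iterations_per_session=2,
                    frames_per_gesture=3, gain_spread=0.0, rotation_prob=0.0,
                    drift_amplitude=0.0, sigma_noise=0.0, seed=3)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
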