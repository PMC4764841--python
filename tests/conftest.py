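import numpy as np
import pytest

import slowfield as sf


@pytest.fixture(scope="session")
def array84():
    return sf.make_sensor_array(84, seed=1)


@pytest.fixture(scope="session")
def array160():
    return sf.make_sensor_array(160, seed=7)


@pytest.fixture(scope="session")
def small_session(array84):
    """Short open-loop session (16 trials) for unit tests."""
    cfg = sf.SimulationConfig(seed=11, cues_per_type=8)
    return sf.simulate_open_loop(cfg, array84)


@pytest.fixture(scope="session")
def small_stats(small_session):
    return sf.compute_baseline_stats(small_session)


@pytest.fixture(scope="session")
def small_features(small_session, small_stats):
    return sf.feature_set_from_session(
        small_session, small_stats, sf.WindowGrid(-2000, 2000, 100))


@pytest.fixture(scope="session")
def default_session(array84):
    """Full-size open-loop session (40 trials per type) at default SNR."""
    return sf.simulate_open_loop(sf.SimulationConfig(seed=3), array84)


@pytest.fixture(scope="session")
def default_stats(default_session):
    return sf.compute_baseline_stats(default_session)


@pytest.fixture(scope="session")
def default_features(default_session, default_stats):
    return sf.feature_set_from_session(
        default_session, default_stats, sf.WindowGrid(-2000, 2000, 100))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_manual_session(data, rate=1000.0, array=None, cues=(), cue_types=()):
    """Wrap a raw data matrix in a MEGSession for feature-level tests."""
    if array is None:
        array = sf.make_sensor_array(
            max(84, data.shape[0]), seed=0)
        if data.shape[0] != array.n_sensors:
            raise ValueError("data rows must match the array")
    return sf.MEGSession(
        data=np.asarray(data, dtype=float),
        rate=rate,
        lowpass=200.0,
        schedule=sf.EventSchedule(
            cue_times=np.asarray(cues, dtype=float),
            cue_types=tuple(cue_types),
            instruction_times=np.array([]),
            instruction_types=(),
        ),
        sensor_array=array,
        seed=0,
        config={},
    )
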