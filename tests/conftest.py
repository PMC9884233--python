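import numpy as np
import pytest

from lateroflux.signal_io import BilateralSession, PerfusionRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_session(left, right, fs=64.0, stimulus_time=900.0, group="30C",
                 subject_id="S001"):
    return BilateralSession(
        left=PerfusionRecording(left, fs=fs, side="left", subject_id=subject_id),
        right=PerfusionRecording(right, fs=fs, side="right", subject_id=subject_id),
        stimulus_time=stimulus_time, group=group, subject_id=subject_id)


@pytest.fixture
def session_factory():
    return make_session


@pytest.fixture
def flat_session():
    """45-min constant-perfusion session (identical sides)."""
    n = int(2700 * 64)
    x = np.full(n, 20.0)
    return make_session(x, x.copy())
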