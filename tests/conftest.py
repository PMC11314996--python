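import numpy as np
import pytest

from gazemend import DEFAULT_GEOMETRY, GazeRecording, build_default_schedule


@pytest.fixture(scope="session")
def geom():
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def schedule():
    return build_default_schedule()


def make_recording(x, y=None, t=None, valid=None, rate_hz=1000.0):
    """Small hand-built recording helper used across test modules."""
    x = np.asarray(x, dtype=float)
    if y is None:
        y = np.zeros_like(x)
    if t is None:
        t = np.arange(len(x), dtype=float) * (1000.0 / rate_hz)
    return GazeRecording(t=np.asarray(t, float), x=x, y=np.asarray(y, float), valid=valid, sampling_rate_hz=rate_hz)


@pytest.fixture
def constant_trace():
    n = 2000
    return make_recording(np.full(n, 840.0), np.full(n, 525.0))
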