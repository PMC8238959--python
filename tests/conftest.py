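import numpy as np
import pytest

from ranevs.gaze_io import GazeTrace
from ranevs.stimuli import (DEFAULT_SCREEN, RunSpec, StimulusType,
                            build_array_layout)


@pytest.fixture(scope="session")
def screen():
    return DEFAULT_SCREEN


@pytest.fixture(scope="session")
def array():
    return build_array_layout(StimulusType.OBJECT, 1)


@pytest.fixture(scope="session")
def symbolic_array():
    return build_array_layout(StimulusType.NUMBER, 1)


@pytest.fixture
def run_spec():
    return RunSpec("p01", StimulusType.OBJECT, 1)


def make_trace(t, x, y, valid=None, run_spec=None, rate=60.0):
    """Binocular trace from a single gaze path (both eyes at the point)."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if valid is None:
        valid = np.ones(t.size, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    rs = run_spec or RunSpec("p01", StimulusType.OBJECT, 1)
    xs = np.where(valid, x, 0.0)
    ys = np.where(valid, y, 0.0)
    return GazeTrace(run_spec=rs, t=t, lx=xs, ly=ys, lvalid=valid,
                     rx=xs, ry=ys, rvalid=valid, nominal_rate_hz=rate)


@pytest.fixture
def trace_factory():
    return make_trace
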