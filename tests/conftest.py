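import numpy as np
import pytest

from protact import VoltageTrace


@pytest.fixture
def sine_trace():
    """Unit-amplitude 5 Hz sine, 10 s at 1 kHz."""
    dt = 1e-3
    t = np.arange(0, 10, dt)
    return VoltageTrace(t=t, v=np.sin(2 * np.pi * 5 * t), dt=dt, label="5Hz")


@pytest.fixture
def constant_trace():
    return VoltageTrace.from_samples(np.full(100, 0.3), dt=0.01, label="const")


def make_trace(v, dt=0.01, label=""):
    return VoltageTrace.from_samples(np.asarray(v, float), dt=dt, label=label)
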