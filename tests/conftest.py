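import numpy as np
import pytest

from dendricap.core import Trace, VoltageStepProtocol
from dendricap.spike_features import SpikeConfig


@pytest.fixture
def protocol():
    """Standard capacitance step: -80 to -90 mV, 1 s, onset at 10 ms."""
    return VoltageStepProtocol()


@pytest.fixture
def nofilter_cfg():
    """Spike config with the low-pass disabled, for exact-geometry fixtures."""
    return SpikeConfig(filter_cutoff_khz=None)


def make_triangle_trace(
    v_base=-60.0,
    v_peak=40.0,
    rise_ms=1.0,
    fall_ms=1.0,
    dt=0.01,
    pad_ms=5.0,
):
    """A single triangular spike with the apex on the sample grid."""
    n = int(round((pad_ms * 2 + rise_ms + fall_ms) / dt))
    t = np.arange(n) * dt
    v = np.full(n, v_base)
    t_on = pad_ms
    rise = (t >= t_on) & (t < t_on + rise_ms)
    v[rise] = v_base + (v_peak - v_base) * (t[rise] - t_on) / rise_ms
    fall = (t >= t_on + rise_ms) & (t < t_on + rise_ms + fall_ms)
    v[fall] = v_peak - (v_peak - v_base) * (t[fall] - t_on - rise_ms) / fall_ms
    return Trace(samples=v, dt=dt, kind="voltage")
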