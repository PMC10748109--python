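import numpy as np
import pytest

from cellwatch.core import DAY_SECONDS, Channel, ChannelSeries


def make_series(values, interval_s=10.0, channel=Channel.GLU, active=None):
    values = np.asarray(values, dtype=float)
    t = np.arange(values.size) * interval_s / DAY_SECONDS
    return ChannelSeries(channel, t, values, active)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noisy_series(rng):
    return make_series(20.0 + rng.normal(0, 0.1, size=600))
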