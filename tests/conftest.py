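import numpy as np
import pytest

from ecogplv import (
    AnalysisConfig,
    ChannelInfo,
    EventTable,
    RecordingBundle,
)


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_bundle(signals, fs=1000.0, regions=None, groups=None, seeds=(),
                events=None, session_id="test"):
    """Small hand-rolled bundle for unit tests."""
    signals = np.asarray(signals, dtype=np.float32)
    n_ch = signals.shape[0]
    regions = regions or ["other"] * n_ch
    groups = groups if groups is not None else [0] * n_ch
    channels = [
        ChannelInfo(f"c{i:02d}", regions[i], groups[i], is_seed=(f"c{i:02d}" in seeds))
        for i in range(n_ch)
    ]
    return RecordingBundle(signals, fs, channels, session_id, events)


@pytest.fixture
def tone_events():
    return EventTable([500.0, 1000.0, 1500.0], ["tone", "omission", "tone"])
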