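import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for edf_writer helper

from somnoscale.recordings import ChannelInfo, Epoch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_epoch(rng):
    """Two-channel 60 s epoch of plain Gaussian noise at 200 Hz."""
    return Epoch(samples=rng.standard_normal((2, 12000)), fs=200.0,
                 state="N3",
                 channels=[ChannelInfo("LA1", "p01", 37),
                           ChannelInfo("LO2", "p01", 4)])
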