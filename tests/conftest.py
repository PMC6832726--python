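import numpy as np
import pytest

import gaitqual as gq
from gaitqual.features import FeatureConfig

FS = 100.0


def axis_epoch(x, fs=FS):
    """Epoch carrying the same signal on all three axes (aligned)."""
    return gq.AccelEpisode(np.column_stack([x, x, x]), fs, aligned=True)


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def noiseless_episode():
    """30 s perfectly periodic gait episode, stride 0.9 strides/s."""
    params = gq.GaitSignalParams(duration_s=30, fs=FS, f_stride=0.9, seed=3)
    return gq.simulate_gait_episode(params)


@pytest.fixture(scope="session")
def noiseless_epoch(noiseless_episode):
    aligned = gq.realign_axes(noiseless_episode)
    return gq.split_epochs(aligned, 10.0)[0]


@pytest.fixture(scope="session")
def jittered_epoch():
    """10 s epoch with per-stride phase jitter and sensor noise."""
    params = gq.GaitSignalParams(duration_s=12, fs=FS, f_stride=0.9,
                                 phase_jitter_sd=0.2, noise_sd=0.02, seed=11)
    aligned = gq.realign_axes(gq.simulate_gait_episode(params))
    return gq.split_epochs(aligned, 10.0)[0]


@pytest.fixture(scope="session")
def config():
    return FeatureConfig()
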