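import numpy as np
import pytest

from sarcoquant import synth
from sarcoquant.profiles import LineProfile
from sarcoquant.synth.geometry import ChannelBands, NoiseSpec, SarcomereGeometry


@pytest.fixture(scope="session")
def larval_geometry():
    return synth.build_geometry(synth.load_preset("larval"))


@pytest.fixture(scope="session")
def flight_geometry():
    return synth.build_geometry(synth.load_preset("flight"))


@pytest.fixture(scope="session")
def larval_profiles(larval_geometry):
    """Noise-free larval two-channel profiles plus the truth table."""
    return synth.make_striated_profile(larval_geometry, 0.05)


@pytest.fixture
def single_gaussian_profile():
    """Exact Gaussian band A=10, mu=5, sigma=0.3 on a fine grid."""
    x = (np.arange(400) + 0.5) * 0.025
    y = 10.0 * np.exp(-((x - 5.0) ** 2) / (2 * 0.3**2))
    return LineProfile(x, y, channel="test")


def gaussian_noise(sd, seed):
    return NoiseSpec("gaussian", sd, seed=seed)


def point_geometry(length, offsets_by_channel, psf_sigma, n_periods, amplitude=100.0):
    channels = {
        name: ChannelBands("point", tuple(offs), amplitude)
        for name, offs in offsets_by_channel.items()
    }
    return SarcomereGeometry(length, channels, psf_sigma, n_periods)
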