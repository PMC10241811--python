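import numpy as np
import pytest

from hierflux import fibonacci_sphere, make_gradient
from hierflux.core import RegionTimeSeries


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def gradient200():
    return make_gradient(200).primary


@pytest.fixture(scope="session")
def sphere1000():
    return fibonacci_sphere(1000)


@pytest.fixture()
def small_ts(rng):
    """20 regions x 400 frames of white noise at an fMRI-like dt."""
    return RegionTimeSeries(rng.standard_normal((400, 20)), dt=0.72)


def sinusoid_ts(freq_hz, n_frames, dt, amplitude=1.0, n_regions=1, phase=0.0):
    t = np.arange(n_frames) * dt
    x = amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
    return RegionTimeSeries(np.tile(x[:, None], (1, n_regions)), dt)
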