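import numpy as np
import pytest

from swemg import build_default_grid, severity_preset, simulate_recording
from swemg.recording import Recording


@pytest.fixture(scope="session")
def grid():
    return build_default_grid()


@pytest.fixture(scope="session")
def healthy_recording(grid):
    """One 'none'-severity synthetic trial, reused by read-only tests."""
    return simulate_recording(severity_preset("none", seed=7), grid)


def make_noise_recording(n_samples=3000, fs=1000.0, seed=0, scale=1.0,
                         **meta) -> Recording:
    rng = np.random.default_rng(seed)
    return Recording(signal=scale * rng.standard_normal((n_samples, 64)),
                     fs=fs, **meta)


@pytest.fixture
def noise_recording():
    return make_noise_recording(seed=3)
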