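import numpy as np
import pytest

from emid.epoching import epoch_subject
from emid.montage import build_montage, default_placement
from emid.preprocess import preprocess
from emid.synthetic import SynthConfig, generate_subject

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def montage():
    return build_montage(list(default_placement()))


@pytest.fixture(scope="session")
def small_config():
    """One-run session: 42 trials balanced over the 7 classes."""
    return SynthConfig(n_runs=1, seed=5)


@pytest.fixture(scope="session")
def small_subject(small_config):
    return generate_subject(small_config)


@pytest.fixture(scope="session")
def small_subject_128(small_subject):
    return preprocess(small_subject)


@pytest.fixture(scope="session")
def small_epochs(small_subject_128, montage):
    epochs, qc = epoch_subject(small_subject_128, montage)
    return epochs


def smoothstep(n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)
    return t * t * (3.0 - 2.0 * t)


@pytest.fixture
def motion_fixture():
    """Factory for noisy motion traces with a known movement start."""

    def make(seed: int, fs: int = 512, start_s: float = 2.5, rise_s: float = 0.3,
             noise_sd: float = 0.1, dur_s: float = 5.0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.0, noise_sd, int(dur_s * fs))
        start = int(start_s * fs)
        n_rise = int(rise_s * fs)
        x[start : start + n_rise] += smoothstep(n_rise)
        x[start + n_rise :] += 1.0
        return x, start

    return make
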