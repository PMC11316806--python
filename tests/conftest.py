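import numpy as np
import pytest

from tactosense import SpikeTrain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_train(rng, n_max=6, duration=100.0):
    """Small random spike train for metric oracles."""
    n = int(rng.integers(0, n_max + 1))
    times = np.sort(rng.uniform(0, duration, size=n))
    # enforce strict increase
    times = np.unique(np.round(times, 6))
    return SpikeTrain(times, duration=duration)


@pytest.fixture
def make_train():
    def _make(times, duration=1000.0, unit_type="SAI"):
        return SpikeTrain(np.asarray(times, dtype=float), duration=duration,
                          unit_type=unit_type)
    return _make
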