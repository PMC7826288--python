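import numpy as np
import pytest

from teloforce.constructs import build_hairpin


@pytest.fixture(scope="session")
def long_hairpin():
    return build_hairpin(long=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_staircase(levels, dwells_samples, noise_sd=0.0, rng=None):
    """Piecewise-constant signal with known change points."""
    parts = [np.full(n, lv, dtype=float)
             for lv, n in zip(levels, dwells_samples)]
    y = np.concatenate(parts)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(y))
    changes = np.cumsum(dwells_samples)[:-1]
    return y, changes.tolist()


@pytest.fixture
def staircase():
    return make_staircase
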