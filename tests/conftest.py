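import numpy as np
import pytest

from nirselect.dataset import SpectraSet


def make_planted(seed, n=80, p=60, informative=None, coefs=None, noise=0.3):
    """Random design with y depending linearly on a few planted channels."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if informative is None:
        informative = (p // 5, p // 2, (4 * p) // 5)
    beta = np.zeros(p)
    beta[list(informative)] = 1.0 if coefs is None else coefs
    y = X @ beta + noise * rng.normal(size=n)
    return SpectraSet(X, np.arange(p, dtype=float) + 1000.0, y=y)


@pytest.fixture
def planted_spectra():
    return make_planted


@pytest.fixture
def small_spectra():
    """20 x 12 random spectra with a linear y, fixed seed."""
    return make_planted(0, n=20, p=12, informative=(2, 7), noise=0.1)
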