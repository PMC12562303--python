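import numpy as np
import pytest

from ordspec import generators


@pytest.fixture(scope="session")
def logistic_chaotic():
    """One chaotic logistic-map series (r=4, T=2000, burn-in 1000)."""
    return generators.logistic(r=4.0, T=2000, burn_in=1000, seed=101)


@pytest.fixture(scope="session")
def logistic_periodic():
    """One periodic-window logistic-map series (r=3.55, T=2000)."""
    return generators.logistic(r=3.55, T=2000, burn_in=1000, seed=101)


@pytest.fixture(scope="session")
def white_noise():
    return generators.gaussian_noise(T=2000, seed=202)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
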