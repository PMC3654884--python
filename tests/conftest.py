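import numpy as np
import pytest

import rawalk


@pytest.fixture(scope="session")
def mixture_table():
    """Well-separated 3-class Gaussian mixture, 150 x 8."""
    spec = rawalk.MixtureSpec(n_per_class=(50, 50, 50), d=8, separation=6.0, seed=1)
    return rawalk.gaussian_mixture_dataset(spec)


@pytest.fixture(scope="session")
def small_table():
    """Tiny 2-class mixture for fast fit/predict tests."""
    spec = rawalk.MixtureSpec(n_per_class=(6, 6), d=3, separation=5.0, seed=7)
    return rawalk.gaussian_mixture_dataset(spec)


@pytest.fixture(scope="session")
def pseaa_params():
    return rawalk.PseAAParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_stochastic_chain(rng, n, alpha, t):
    """Random W -> P -> Q -> Q^t chain for stochasticity checks."""
    W = rng.uniform(0.01, 1.0, size=(n, n))
    W = (W + W.T) / 2
    P = rawalk.transition_from_weights(W)
    Q = rawalk.lazy_operator(P, alpha)
    return rawalk.walk_power(Q, t)
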