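import numpy as np
import pytest

import coexseg as cx


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_f():
    return cx.DEFAULT_F


@pytest.fixture(scope="session")
def default_g():
    return cx.DEFAULT_G


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated arm shared by read-only tests."""
    return cx.simulate_dataset(40, 5, rng=7)


def random_mixture(rng: np.random.Generator) -> cx.MixtureParams:
    """A random but well-conditioned two-normal mixture."""
    return cx.MixtureParams(
        phi=float(rng.uniform(0.1, 0.9)),
        mu1=float(rng.uniform(-3, 1)),
        sigma1=float(rng.uniform(0.3, 2.0)),
        mu2=float(rng.uniform(1, 5)),
        sigma2=float(rng.uniform(0.3, 2.0)),
    )
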