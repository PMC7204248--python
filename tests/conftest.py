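import numpy as np
import pytest

import survcuts as sc


@pytest.fixture(scope="session")
def toy_dataset():
    """Times {3, 5+, 7, 9+}: events at 3 and 7."""
    return sc.SurvivalDataset((3, 5, 7, 9), (1, 0, 1, 0))


@pytest.fixture(scope="session")
def toy_curve(toy_dataset):
    return sc.km_estimate(toy_dataset)


def make_censored_dataset(rng, n=60, admin=None):
    """A random Weibull dataset with administrative censoring."""
    shape = rng.uniform(0.7, 1.8)
    scale = rng.uniform(5.0, 20.0)
    t = scale * rng.weibull(shape, n)
    cens = rng.uniform(0.6, 1.6) * scale if admin is None else admin
    e = (t <= cens).astype(int)
    t = np.minimum(t, cens)
    t = np.maximum(t, 1e-6)
    return sc.SurvivalDataset(tuple(t), tuple(e))


@pytest.fixture(scope="session")
def sim_dataset():
    """One medium simulated dataset shared across fitting tests."""
    rng = np.random.default_rng(20240211)
    return make_censored_dataset(rng, n=200, admin=18.0)


@pytest.fixture(scope="session")
def default_params():
    return sc.default_generator_params()
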