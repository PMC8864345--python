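import numpy as np
import pytest

from metacompare import MetaDataset


def random_dataset(rng, k=None, mu=0.3, tau2=0.1, n_range=(20, 200)):
    """Small random meta-analysis for oracle comparisons."""
    if k is None:
        k = int(rng.integers(2, 11))
    n = rng.integers(n_range[0], n_range[1] + 1, size=k)
    v = 4.0 / n
    theta = rng.normal(mu, np.sqrt(tau2), size=k)
    y = rng.normal(theta, np.sqrt(v))
    return MetaDataset.from_arrays(y, v)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_dataset():
    """Five-study fixture used for frozen reference values."""
    return MetaDataset.from_arrays(
        [0.10, 0.30, 0.35, 0.65, 0.20],
        [0.015, 0.020, 0.010, 0.025, 0.030],
        phenomenon_id="fixture",
    )
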