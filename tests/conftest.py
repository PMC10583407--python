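import numpy as np
import pytest

from sparse_llgmn import AnalysisConfig, FeatureTable, standardize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_table():
    """Tiny two-class table with one informative column."""
    rng = np.random.default_rng(0)
    n = 40
    x = rng.normal(0, 1, (n, 3))
    x[: n // 2, 0] += 2.0
    labels = np.r_[np.ones(n // 2, int), 2 * np.ones(n // 2, int)]
    return FeatureTable(x, labels, ["informative", "noise_a", "noise_b"])


@pytest.fixture
def toy_std(toy_table):
    return standardize(toy_table)


@pytest.fixture
def separable_table():
    """Well-separated 2-D Gaussians (centers +-2): near-zero Bayes error."""
    rng = np.random.default_rng(7)
    n = 100
    x = rng.normal(0, 1, (n, 2))
    x[: n // 2] += 2.0
    x[n // 2 :] -= 2.0
    labels = np.r_[np.ones(n // 2, int), 2 * np.ones(n // 2, int)]
    return standardize(FeatureTable(x, labels, ["u", "v"]))


@pytest.fixture
def fast_config():
    return AnalysisConfig(lam=0.0, max_epochs=100, seed=0)
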