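import numpy as np
import pytest

from kfdiff import Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture
def gaussian_pair():
    """Factory: two multivariate-Gaussian samples as one Dataset."""

    def make(n1=40, n2=40, p=2, shift=1.0, seed=0, scale=1.0):
        r = np.random.default_rng(seed)
        X = np.vstack(
            [r.normal(0.0, scale, (n1, p)), r.normal(shift, scale, (n2, p))]
        )
        return Dataset(X, ["a"] * n1 + ["b"] * n2)

    return make


@pytest.fixture
def toy_univariate():
    """Three 1-feature cells {0, 1, 3} across two conditions."""
    return Dataset(np.array([[0.0], [1.0], [3.0]]), ["a", "a", "b"])
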