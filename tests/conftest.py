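import numpy as np
import pytest

import rpilearn as rp


@pytest.fixture(scope="session")
def small_dataset():
    """40 balanced synthetic pairs with a fully planted motif signal."""
    return rp.generate(rp.SynthConfig(n_pairs=40, seed=101))


@pytest.fixture(scope="session")
def signal_dataset():
    """200 balanced pairs, the scale used for end-to-end protocol checks."""
    return rp.generate(rp.SynthConfig(n_pairs=200, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_psd_gram(rng, m):
    """Random unit-diagonal PSD matrix (a valid normalized Gram)."""
    X = rng.normal(size=(m, m + 3))
    X /= np.linalg.norm(X, axis=1, keepdims=True)
    return X @ X.T
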