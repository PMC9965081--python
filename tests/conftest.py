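import numpy as np
import pytest

import cefhar as ch


@pytest.fixture(scope="session")
def catalog():
    return ch.canonical_catalog()


@pytest.fixture(scope="session")
def small_dataset():
    """2 subjects x 18 scripts x 2 reps = 72 protocol samples."""
    return ch.generate_dataset(ch.GeneratorConfig(n_subjects=2, reps=2, seed=3))


@pytest.fixture(scope="session")
def micro_model_config():
    """A very small but structurally complete model for fast training tests."""
    return ch.ModelConfig(
        kernel_sizes=(5, 10),
        filters=8,
        n_blocks=1,
        reduction=4,
        seq_len=250,
        layer_norm="feature_map",
    )


def numeric_gradient(f, x, eps=1e-6):
    """Central finite differences of a scalar function of one array."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
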