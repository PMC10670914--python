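import numpy as np
import pytest

from swarmlayer import FeatureTable, SynthSpec, generate_two_class_features


@pytest.fixture
def small_table():
    """60x8 two-class table with a mild 1-sigma class gap."""
    return generate_two_class_features(
        SynthSpec(n_class0=30, n_class1=30, dim=8, mean_shift=1.0, seed=7)
    )


@pytest.fixture
def separable_table():
    """2000-sample strongly separated table (4-sigma gap on half the dims)."""
    return generate_two_class_features(
        SynthSpec(n_class0=1000, n_class1=1000, dim=32, mean_shift=4.0, seed=0)
    )


@pytest.fixture
def tiny_features():
    return np.array([0.5, -1.2, 2.0, 0.1, 1.4, -0.7, 0.9, 1.1])


def make_table(n, d, seed=0):
    rng = np.random.default_rng(seed)
    return FeatureTable(rng.normal(size=(n, d)), rng.integers(0, 2, size=n))
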