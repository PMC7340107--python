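import numpy as np
import pytest

from spikecompat.cluster import Partition
from spikecompat.features import pca_features
from spikecompat.simulate import SimConfig, simulate_waveform_pool


@pytest.fixture(scope="session")
def low_pool():
    """Balanced 3-class low-similarity pool at the benchmark-like low noise."""
    return simulate_waveform_pool(
        SimConfig(n_classes=3, n_spikes=600, similarity="low", noise_sd=0.05, seed=7)
    )


@pytest.fixture(scope="session")
def high_pool():
    return simulate_waveform_pool(
        SimConfig(n_classes=3, n_spikes=600, similarity="high", noise_sd=0.05, seed=7)
    )


@pytest.fixture(scope="session")
def low_features(low_pool):
    return pca_features(low_pool, label="Epca")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def two_cluster_1d():
    """The 1-D hand fixture {0,2} and {10,14}: BH 2.5, TrW 10, DB 3/11."""
    X = np.array([[0.0], [2.0], [10.0], [14.0]])
    labels = Partition(labels=np.array([1, 1, 2, 2]))
    return X, labels
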