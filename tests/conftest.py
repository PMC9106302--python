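import warnings

import numpy as np
import pytest

from boundarykit import (SyntheticConfig, plant_truth, simulate_matrix,
                         ice_normalize)
from boundarykit.hic import ContactMatrix

# balancing warnings on tiny noisy fixtures are expected
warnings.filterwarnings("ignore", message="ICE did not converge")


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(arm_length=400_000, n_boundaries=4,
                           sequencing_depth=100_000, seed=42)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return plant_truth(small_config)


@pytest.fixture(scope="session")
def balanced_matrix(small_config, small_truth):
    mat = simulate_matrix(small_truth, small_config)
    return ice_normalize(mat)


def random_symmetric_matrix(n, rng, low=0.5, high=2.0):
    m = rng.uniform(low, high, size=(n, n))
    return (m + m.T) / 2


def uniform_matrix(n, value=1.0, bin_size=2000):
    mat = ContactMatrix(chrom="chrU", bin_size=bin_size,
                        counts=np.full((n, n), value))
    mat.mask = np.ones(n, dtype=bool)
    mat.normalized = mat.counts.copy()
    return mat
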