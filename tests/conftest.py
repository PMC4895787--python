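import numpy as np
import pytest

from coalmap import SimParams, infer_breakpoints, simulate_alignment
from coalmap.covariates import CovariateBuilder

# small but structurally realistic dataset shared by several test modules
SMALL_PARAMS = SimParams(
    gamma=0.5, theta_per_locus=8.0, num_loci=5, n_A=20, n_B=20, n_H=20, seed=42
)


@pytest.fixture(scope="session")
def small_alignment():
    return simulate_alignment(SMALL_PARAMS)


@pytest.fixture(scope="session")
def small_partitions(small_alignment):
    return infer_breakpoints(small_alignment)


@pytest.fixture(scope="session")
def small_builder(small_alignment, small_partitions):
    return CovariateBuilder(small_alignment, small_partitions)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
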