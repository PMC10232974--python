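import warnings

import numpy as np
import pytest

from fcsubnet import decomposition as dc
from fcsubnet import pruning
from fcsubnet.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Standard planted cohort: K=30, 20+20 subjects, 4 components."""
    return generate_cohort(SyntheticConfig(seed=5))


@pytest.fixture(scope="session")
def decomposed(cohort):
    """PCA + 10-run ICA ensemble + RAICAR ranking of the standard cohort."""
    stack, _ = cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        reduced, ranked = dc.decompose(stack, n_runs=10, seed=42, n_select=8)
    return reduced, ranked


@pytest.fixture(scope="session")
def subnetworks(decomposed):
    _, ranked = decomposed
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return pruning.prune(ranked)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
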