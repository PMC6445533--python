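import numpy as np
import pytest

from chipsim import load_config, run_experiment
from chipsim.motif import toy_matrix


@pytest.fixture(scope="session")
def matrix():
    return toy_matrix()


@pytest.fixture(scope="session")
def default_result():
    """One full-scale reference experiment (paper defaults), shared."""
    return run_experiment(load_config(seed=11))


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size config for fast per-test simulations."""
    return load_config(n_loci=200, n_cells=20_000, depth=50, seed=7)


@pytest.fixture(scope="session")
def small_result(small_config):
    return run_experiment(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
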