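import numpy as np
import pytest

import safbreed as sb


@pytest.fixture(scope="session")
def small_pop():
    """A 100 x 300 founder panel used across unit tests."""
    return sb.simulate_founders(sb.FounderConfig(n_individuals=100, n_markers=300, seed=1))


@pytest.fixture(scope="session")
def small_arch(small_pop):
    return sb.simulate_trait_architecture(small_pop, n_qtl=60, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
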