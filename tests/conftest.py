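import numpy as np
import pytest

from phylostruct import (DemeParameters, SimulationConfig,
                         simulate_structured_tree, simulate_unstructured_tree,
                         worked_example_tree)


@pytest.fixture
def example_tree():
    """Five-tip structured tree with one migration node (worked example)."""
    return worked_example_tree()


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_structured_tree(seed, n_tips=(15, 10), death=0.05):
    """Small structured tree for property tests (deaths exercise pruning)."""
    params = (DemeParameters(1.0, death, 0.3),
              DemeParameters(1.4, death, 0.2))
    return simulate_structured_tree(
        params, SimulationConfig(n_tips=n_tips),
        np.random.default_rng(seed))


def random_unstructured_tree(seed, n_tips=20, death=0.2):
    return simulate_unstructured_tree(1.0, death, n_tips,
                                      np.random.default_rng(seed))
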