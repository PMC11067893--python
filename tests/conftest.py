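import numpy as np
import pytest

from mitoconcord import SimulationConfig, SubstitutionModel, simulate_tree


def random_tree(n_taxa: int, seed: int, height: float | None = None):
    """A random fully resolved rooted tree, deterministic under seed."""
    cfg = SimulationConfig(
        seed=seed, n_taxa=n_taxa, partition_spec={"g": 10}, tree_height_scale=height
    )
    return simulate_tree(cfg)


@pytest.fixture
def jc_model():
    return SubstitutionModel()


@pytest.fixture
def gtr_model():
    return SubstitutionModel(
        exchangeabilities=(1.0, 4.0, 1.0, 1.0, 4.0, 1.0),
        base_freqs=(0.35, 0.30, 0.12, 0.23),
        p_invariant=0.2,
        gamma_shape=0.7,
        n_categories=4,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240430)
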