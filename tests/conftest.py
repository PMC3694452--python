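import numpy as np
import pytest

from sisterrates.models import NucModel
from sisterrates.simulate import SimulationConfig, simulate_pair_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_tree(rng, n_tips=6, height=0.4):
    """A random ultrametric pair-style tree for property tests."""
    cfg = SimulationConfig(
        n_pairs=1,
        tips_per_clade=max(1, n_tips // 2),
        clade_height=height / 3,
        stem_length=height / 6,
        outgroup_depth=height,
        model=NucModel(ncat=1),
        seq_length=10,
        seed=int(rng.integers(2**31)),
    )
    tree, pair = simulate_pair_tree(cfg, 1, rng)
    return tree, pair
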