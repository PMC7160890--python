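import numpy as np
import pytest

from qconstree.simulate import random_binary_tree
from qconstree.tree import contract_edges, bipartitions


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tree(labels, rng, multifurcating=False, p_contract=0.3):
    """Random (optionally multifurcating) unrooted tree for tests."""
    t = random_binary_tree(labels, rng)
    if multifurcating:
        splits = sorted(bipartitions(t),
                        key=lambda s: sorted(sorted(side) for side in s))
        drop = [s for s in splits if rng.random() < p_contract]
        if drop:
            t = contract_edges(t, drop)
    return t


def labels(n):
    return [chr(97 + i) for i in range(n)] if n <= 26 else \
        [f"t{i:03d}" for i in range(n)]
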