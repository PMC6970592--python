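import numpy as np
import pytest

from dimorphasr import simulate_tree


def random_tree(rng, n_leaves, jitter=True):
    """Random tree via the Yule generator, optionally with lognormal-jittered
    (non-ultrametric) branch lengths."""
    tree = simulate_tree(n_leaves, 1.0, rng)
    if jitter:
        for node in tree.postorder():
            if node is not tree.root:
                node.length = float(node.length * rng.lognormal(0.0, 0.5))
    return tree


def random_tips(rng, tree, states):
    return {label: states[rng.integers(len(states))]
            for label in tree.leaf_labels()}


@pytest.fixture
def rng():
    return np.random.default_rng(20200117)
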