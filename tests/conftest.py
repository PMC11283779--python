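import numpy as np
import pytest

from ouregimes.phylo import read_tree_string
from ouregimes.regime_mapping import RegimeMap


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):0.5,C:1.5); ultrametric, depth 1.5."""
    return read_tree_string("((A:1,B:1):0.5,C:1.5);")


@pytest.fixture
def cherry():
    return read_tree_string("(A:1,B:1);")


def random_tree(rng, n_tips, depth=None):
    """Random topology with exponential branch lengths (non-ultrametric)."""
    from ouregimes.synthetic_data import simulate_tree
    tree = simulate_tree(n_tips, birth=0.3, death=0.0,
                         depth=depth or 1.0, seed=int(rng.integers(2 ** 31)))
    # perturb tip branch lengths so trees are non-ultrametric in general
    lengths = tree.lengths.copy()
    for t in tree.tips:
        lengths[t] *= rng.uniform(0.5, 1.5)
    from ouregimes.phylo import Phylogeny
    return Phylogeny(tree.parent, lengths, tree.labels)


def random_regime_map(rng, tree, states=("r1", "r2")):
    from ouregimes.synthetic_data import simulate_regimes
    return simulate_regimes(tree, q=1.0 / max(tree.height, 1e-9), root_regime=states[0],
                            regimes=states, seed=int(rng.integers(2 ** 31)))


def mvn_logpdf(y, mean, cov):
    """Brute-force multivariate-normal log-density (independent oracle)."""
    from scipy.stats import multivariate_normal
    return float(multivariate_normal(mean=mean, cov=cov, allow_singular=False).logpdf(y))
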