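import numpy as np
import pytest

from phylorepro import (
    SearchConfig,
    generate_model_tree,
    hky,
    simulate_alignment,
)


@pytest.fixture
def hky_model():
    return hky(2.0, (0.3, 0.2, 0.2, 0.3))


@pytest.fixture
def small_instance(hky_model):
    """A well-resolved 6-taxon data set with strong signal."""
    tree = generate_model_tree(6, 2.0, seed=101)
    aln = simulate_alignment(tree, hky_model, 2000, seed=102)
    return tree, aln, hky_model


@pytest.fixture
def weak_instance(hky_model):
    """A low-information 10-taxon data set (short tree, few sites)."""
    tree = generate_model_tree(10, 0.1, seed=201)
    aln = simulate_alignment(tree, hky_model, 150, seed=202)
    return tree, aln, hky_model
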