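import numpy as np
import pytest

from morphoclade.matrix import CharacterMatrix, CharacterMeta
from morphoclade.simulate import (SimulationConfig, simulate_matrix,
                                  simulate_tree)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_matrix():
    """Deterministic 7-taxon, 30-character simulated matrix with missing
    data and polymorphism."""
    config = SimulationConfig(n_taxa=7, n_chars=30, seed=3,
                              missing_rate=0.05, polymorphism_rate=0.03,
                              tree_depth=0.8)
    tree = simulate_tree(config)
    return simulate_matrix(tree, config)


@pytest.fixture
def small_tree():
    config = SimulationConfig(n_taxa=7, n_chars=30, seed=3, tree_depth=0.8)
    return simulate_tree(config)


def make_matrix(taxa, columns, ks=None, ordered=None):
    """Build a CharacterMatrix from per-character column lists of
    state sets."""
    n_char = len(columns)
    ks = ks or [max(max(c) for cell in col for c in [cell]) + 1
                for col in columns]
    ks = [max(k, 2) for k in ks]
    ordered = ordered or [False] * n_char
    meta = [CharacterMeta(index=j + 1, k=ks[j], ordered=ordered[j])
            for j in range(n_char)]
    cells = [[frozenset(columns[j][i]) for j in range(n_char)]
             for i in range(len(taxa))]
    return CharacterMatrix(taxa=list(taxa), cells=cells, char_meta=meta)
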