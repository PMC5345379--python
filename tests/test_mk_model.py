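"""Mk/Mkv likelihood engine against closed forms and enumeration."""

import itertools

import numpy as np
import pytest

from morphoclade.matrix import CharacterMatrix, CharacterMeta
from morphoclade.mk import (LikelihoodEngine, MkModelSpec, character_loglik,
                            gamma_rates, matrix_loglik, rate_matrix,
                            transition_probs)
from morphoclade.simulate import (SimulationConfig, simulate_matrix,
                                  simulate_tree)
from morphoclade.trees import Node, PhyloTree, random_topology

from oracles import brute_loglik


class TestRateMatrix:
    def test_two_state_forced_form(self):
        assert np.allclose(rate_matrix(2), [[-1, 1], [1, -1]])

    @pytest.mark.parametrize("k", [2, 3, 4, 6])
    @pytest.mark.parametrize("ordered", [False, True])
    def test_normalised_to_one_expected_change(self, k, ordered):
        Q = rate_matrix(k, ordered)
        pi = np.full(k, 1.0 / k)
        assert np.isclose(-(pi * np.diag(Q)).sum(), 1.0)
        assert np.allclose(Q.sum(axis=1), 0.0)

    def test_ordered_has_no_long_jumps(self):
        Q = rate_matrix(3, ordered=True)
        assert Q[0, 2] == Q[2, 0] == 0.0

    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            rate_matrix(1)


class TestTransitionProbs:
    def test_zero_length_is_identity(self):
        assert np.allclose(transition_probs(rate_matrix(3), 0.0), np.eye(3))

    def test_binary_closed_form(self):
        P = transition_probs(rate_matrix(2), 0.1)
        assert P[0, 0] == pytest.approx(0.5 + 0.5 * np.exp(-0.2), abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_long_branch_reaches_stationarity(self, k):
        P = transition_probs(rate_matrix(k), 100.0)
        assert np.allclose(P, 1.0 / k, atol=1e-9)

    def test_rows_sum_to_one(self):
        for k, ordered in [(3, False), (4, True)]:
            P = transition_probs(rate_matrix(k, ordered), 0.37, r=1.7)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            transition_probs(rate_matrix(2), -0.1)


def test_gamma_rates_mean_one_and_limits():
    for alpha in (0.1, 0.5, 2.0):
        rates = gamma_rates(alpha, 4)
        assert rates.mean() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(rates) > 0).all()
    assert np.allclose(gamma_rates(1e6, 4), 1.0, atol=1e-2)
    # median-mode discretisation is also mean-one after normalisation
    assert gamma_rates(0.5, 4, mode="median").mean() == pytest.approx(1.0)


def _random_tree(taxa, rng, lo=0.05, hi=0.6):
    tree = random_topology(list(taxa), rng).unroot()
    for e in tree.edges():
        e.length = float(rng.uniform(lo, hi))
    return tree


def _one_char_matrix(taxa, column, k, ordered=False):
    return CharacterMatrix(
        taxa=list(taxa), cells=[[frozenset(c)] for c in column],
        char_meta=[CharacterMeta(index=1, k=k, ordered=ordered)])


class TestCharacterLoglik:
    def test_single_taxon_stationary_prior(self):
        tree = PhyloTree(Node(label="A"))
        p = character_loglik(tree, [frozenset({0})],
                             CharacterMeta(index=1, k=2), MkModelSpec())
        assert p.lnL == pytest.approx(-np.log(2.0), abs=1e-12)

    @pytest.mark.parametrize("gamma", [False, True])
    @pytest.mark.parametrize("k,ordered", [(2, False), (3, False), (3, True)])
    def test_pruning_matches_enumeration(self, gamma, k, ordered, rng):
        spec = MkModelSpec(gamma=gamma, ncat=4, alpha=0.6)
        tree = _random_tree("ABCDE", rng)
        column = [frozenset({int(rng.integers(0, k))}) for _ in range(4)]
        column.append(frozenset({0, 1}))  # one ambiguous leaf
        m = _one_char_matrix(tree.taxa, column, k, ordered)
        lnl = LikelihoodEngine(m, spec).loglik(tree)
        assert lnl == pytest.approx(
            brute_loglik(tree, column, k, ordered, spec.rates()), abs=1e-9)

    def test_rerooting_invariance(self, rng):
        """Pulley principle: the unrooted likelihood does not depend on
        which leaf the traversal hangs from."""
        spec = MkModelSpec(gamma=True, alpha=0.4, conditioning="variable")
        config = SimulationConfig(n_taxa=8, n_chars=25, seed=9,
                                  tree_depth=0.7)
        tree = simulate_tree(config)
        matrix = simulate_matrix(tree, config)
        base = matrix_loglik(tree, matrix, spec)
        for leaf in tree.taxa[:4]:
            rerooted = tree.rooted_on(leaf)
            assert matrix_loglik(rerooted, matrix, spec) == pytest.approx(
                base, abs=1e-9)

    def test_gamma_converges_to_no_gamma(self, rng):
        tree = _random_tree("ABCDEF", rng)
        col = [frozenset({int(rng.integers(0, 2))}) for _ in range(6)]
        m = _one_char_matrix(tree.taxa, col, 2)
        flat = LikelihoodEngine(m, MkModelSpec(gamma=False)).loglik(tree)
        big = LikelihoodEngine(
            m, MkModelSpec(gamma=True, alpha=1e6)).loglik(tree)
        assert abs(flat - big) < 1e-6

    def test_missing_data_never_decreases_likelihood(self, rng):
        tree = _random_tree("ABCDE", rng)
        col = [frozenset({int(rng.integers(0, 3))}) for _ in range(5)]
        m = _one_char_matrix(tree.taxa, col, 3)
        base = LikelihoodEngine(m, MkModelSpec()).per_character(tree)[1].lnL
        for i in range(5):
            relaxed = list(col)
            relaxed[i] = frozenset({0, 1, 2})
            m2 = _one_char_matrix(tree.taxa, relaxed, 3)
            lnl = LikelihoodEngine(m2, MkModelSpec()).per_character(tree)[1].lnL
            assert lnl >= base - 1e-12

    def test_all_missing_column_cannot_condition(self, rng):
        tree = _random_tree("ABCD", rng)
        col = [frozenset({0, 1})] * 4
        m = _one_char_matrix(tree.taxa, col, 2)
        spec = MkModelSpec(conditioning="variable")
        with pytest.raises(ValueError, match="condition"):
            LikelihoodEngine(m, spec).loglik(tree)


class TestConditioning:
    @pytest.mark.parametrize("gamma", [False, True])
    def test_variable_patterns_sum_to_one_star_tree(self, gamma):
        root = Node()
        for t, l in zip("ABC", (0.3, 0.1, 0.5)):
            root.add(Node(label=t, length=l))
        star = PhyloTree(root)
        spec = MkModelSpec(gamma=gamma, alpha=0.7, conditioning="variable")
        total = 0.0
        for pattern in itertools.product((0, 1), repeat=3):
            if len(set(pattern)) == 1:
                continue
            m = _one_char_matrix("ABC", [frozenset({s}) for s in pattern], 2)
            total += np.exp(LikelihoodEngine(m, spec).loglik(star))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_constant_mass_in_open_interval(self, rng):
        tree = _random_tree("ABCD", rng)
        m = _one_char_matrix(tree.taxa,
                             [frozenset({0}), frozenset({1}),
                              frozenset({0}), frozenset({1})], 2)
        p = LikelihoodEngine(
            m, MkModelSpec(conditioning="variable")).per_character(tree)[1]
        assert 0.0 < p.constant_mass < 1.0
        assert p.corrected_lnL == pytest.approx(
            p.lnL - np.log1p(-p.constant_mass), abs=1e-12)


class TestMatrixLoglik:
    def test_empty_matrix_is_zero(self):
        m = CharacterMatrix(taxa=["a", "b", "c", "d"],
                            cells=[[] for _ in range(4)], char_meta=[])
        tree = PhyloTree.from_newick("(a:0.1,b:0.1,(c:0.1,d:0.1):0.1);")
        assert matrix_loglik(tree, m, MkModelSpec()) == 0.0

    def test_duplicated_column_doubles_contribution(self, rng):
        tree = _random_tree("ABCD", rng)
        col = [frozenset({0}), frozenset({1}), frozenset({1}),
               frozenset({0})]
        single = _one_char_matrix(tree.taxa, col, 2)
        double = CharacterMatrix(
            taxa=tree.taxa, cells=[[c, c] for c in col],
            char_meta=[CharacterMeta(index=1, k=2),
                       CharacterMeta(index=2, k=2)])
        spec = MkModelSpec(gamma=True, alpha=0.9)
        assert matrix_loglik(tree, double, spec) == pytest.approx(
            2 * matrix_loglik(tree, single, spec), abs=1e-9)

    def test_total_decomposes_into_characters(self, small_matrix,
                                              small_tree):
        spec = MkModelSpec(gamma=True, alpha=0.5, conditioning="variable")
        engine = LikelihoodEngine(small_matrix, spec)
        total = engine.loglik(small_tree)
        parts = engine.per_character(small_tree)
        assert total == pytest.approx(
            sum(p.corrected_lnL for p in parts.values()), abs=1e-9)
        # and single-character calls agree with the stacked engine
        for idx in list(parts)[:5]:
            meta = small_matrix.char_meta[idx - 1]
            p = character_loglik(small_tree, small_matrix.column(idx),
                                 meta, spec, taxa=small_matrix.taxa)
            assert p.corrected_lnL == pytest.approx(
                parts[idx].corrected_lnL, abs=1e-9)
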