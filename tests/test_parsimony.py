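"""Parsimony scoring, search, consensus, bootstrap and decay."""

import numpy as np
import pytest

from morphoclade.matrix import CharacterMatrix, CharacterMeta
from morphoclade.parsimony import (bootstrap, bremer_decay, character_length,
                                   ensemble_ci, exhaustive_search,
                                   heuristic_search, min_steps,
                                   parsimony_informative_count,
                                   strict_consensus, tree_length)
from morphoclade.simulate import (SimulationConfig, simulate_matrix,
                                  simulate_tree)
from morphoclade.trees import PhyloTree, enumerate_topologies, random_topology

from conftest import make_matrix
from oracles import brute_char_length


class TestCharacterLength:
    def test_constant_column_zero_steps(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        col = [frozenset({1})] * 4
        assert character_length(tree, col, CharacterMeta(index=1, k=2)) == 0

    def test_alternating_four_taxa_two_steps(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        col = {"A": 0, "B": 1, "C": 0, "D": 1}
        column = [frozenset({col[t]}) for t in tree.taxa]
        assert character_length(tree, column,
                                CharacterMeta(index=1, k=2)) == 2

    def test_ordered_distance_two(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        col = {"A": 0, "B": 0, "C": 0, "D": 2}
        column = [frozenset({col[t]}) for t in tree.taxa]
        assert character_length(
            tree, column, CharacterMeta(index=1, k=3, ordered=True)) == 2

    @pytest.mark.parametrize("ordered", [False, True])
    def test_matches_brute_force_on_random_columns(self, ordered, rng):
        for trial in range(8):
            tree = random_topology(list("ABCDEF"), rng).unroot()
            k = 3
            column = [frozenset({int(rng.integers(0, k))}) for _ in range(5)]
            column.append(frozenset({0, 2}))  # ambiguous cell
            got = character_length(
                tree, column, CharacterMeta(index=1, k=k, ordered=ordered))
            assert got == brute_char_length(tree, column, k, ordered)

    def test_unordered_fitch_equals_unit_sankoff(self, rng):
        """A k=2 'ordered' chain is the same model as unordered Fitch."""
        for _ in range(5):
            tree = random_topology(list("ABCDEFG"), rng).unroot()
            column = [frozenset({int(rng.integers(0, 2))}) for _ in range(7)]
            fitch = character_length(tree, column,
                                     CharacterMeta(index=1, k=2))
            sankoff = character_length(
                tree, column, CharacterMeta(index=1, k=2, ordered=True))
            assert fitch == sankoff


class TestTreeLength:
    def test_empty_matrix_zero(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        m = CharacterMatrix(taxa=["A", "B", "C", "D"],
                            cells=[[] for _ in range(4)], char_meta=[])
        assert tree_length(tree, m) == 0

    def test_additive_over_character_blocks(self, small_matrix, small_tree):
        left = CharacterMatrix(
            taxa=small_matrix.taxa,
            cells=[row[:15] for row in small_matrix.cells],
            char_meta=[CharacterMeta(index=j + 1, k=m.k, ordered=m.ordered)
                       for j, m in enumerate(small_matrix.char_meta[:15])])
        right = CharacterMatrix(
            taxa=small_matrix.taxa,
            cells=[row[15:] for row in small_matrix.cells],
            char_meta=[CharacterMeta(index=j + 1, k=m.k, ordered=m.ordered)
                       for j, m in enumerate(small_matrix.char_meta[15:])])
        assert tree_length(small_tree, small_matrix) == \
            tree_length(small_tree, left) + tree_length(small_tree, right)

    def test_invariant_under_rerooting(self, small_matrix, small_tree):
        base = tree_length(small_tree, small_matrix)
        for leaf in small_tree.taxa[:3]:
            assert tree_length(small_tree.rooted_on(leaf),
                               small_matrix) == base


class TestMinSteps:
    def test_three_observed_states_unordered(self):
        col = [frozenset({s}) for s in (0, 1, 2, 0)]
        assert min_steps(col, CharacterMeta(index=1, k=3)) == 2

    def test_ordered_range(self):
        col = [frozenset({0}), frozenset({2})]
        assert min_steps(col, CharacterMeta(index=1, k=3, ordered=True)) == 2

    def test_ambiguity_resolves_to_minimum(self):
        col = [frozenset({0}), frozenset({0, 1}), frozenset({0, 2})]
        assert min_steps(col, CharacterMeta(index=1, k=3)) == 0

    @pytest.mark.parametrize("ordered", [False, True])
    def test_is_minimum_over_all_topologies(self, ordered, rng):
        taxa = list("ABCDE")
        for _ in range(5):
            column = [frozenset({int(rng.integers(0, 3))}) for _ in taxa]
            meta = CharacterMeta(index=1, k=3, ordered=ordered)
            floor = min_steps(column, meta)
            best = min(
                character_length(t, [column[taxa.index(x)] for x in t.taxa],
                                 meta)
                for t in enumerate_topologies(taxa))
            assert floor == best


class TestInformative:
    def test_autapomorphy_not_informative(self):
        m = make_matrix("abcd", [[{1}, {0}, {0}, {0}]])
        assert parsimony_informative_count(m) == 0

    def test_two_by_two_informative(self):
        m = make_matrix("abcd", [[{0}, {0}, {1}, {1}]])
        assert parsimony_informative_count(m) == 1

    def test_polymorphic_support_is_conservative(self):
        # an ambiguous cell does not count toward a state's tally
        m = make_matrix("abcd", [[{0}, {0, 1}, {1}, {1}]])
        assert parsimony_informative_count(m) == 0

    def test_excluded_characters_not_counted(self):
        m = make_matrix("abcd", [[{0}, {0}, {1}, {1}],
                                 [{0}, {1}, {0}, {1}]])
        assert parsimony_informative_count(m.apply_exclusions({2})) == 1


class TestSearch:
    def test_heuristic_equals_exhaustive_on_six_taxa(self):
        config = SimulationConfig(n_taxa=6, n_chars=25, seed=31,
                                  tree_depth=0.8)
        m = simulate_matrix(simulate_tree(config), config)
        ex = exhaustive_search(m)
        h = heuristic_search(m, reps=3, seed=1)
        assert h.length == ex.length
        assert {t.topology_key(m.taxa) for t in h.mpt_set} \
            == {t.topology_key(m.taxa) for t in ex.mpt_set}

    def test_fixed_seed_deterministic(self, small_matrix):
        a = heuristic_search(small_matrix, reps=1, seed=9)
        b = heuristic_search(small_matrix, reps=1, seed=9)
        assert a.length == b.length
        assert [t.to_newick(lengths=False) for t in a.mpt_set] \
            == [t.to_newick(lengths=False) for t in b.mpt_set]

    def test_clean_simulation_recovers_generating_topology(self):
        config = SimulationConfig(n_taxa=12, n_chars=300, seed=41,
                                  tree_depth=0.4, gamma=False)
        tree = simulate_tree(config)
        m = simulate_matrix(tree, config)
        result = heuristic_search(m, reps=2, seed=3)
        keys = {t.topology_key(m.taxa) for t in result.mpt_set}
        assert tree.topology_key(m.taxa) in keys

    def test_ci_definition_and_bounds(self, small_matrix):
        result = heuristic_search(small_matrix, reps=2, seed=7)
        msum = sum(min_steps(small_matrix.column(m.index), m)
                   for m in small_matrix.char_meta if m.included)
        assert result.ci == pytest.approx(msum / result.length)
        assert 0 < result.ci <= 1

    def test_perfect_matrix_has_ci_one(self):
        # two congruent binary characters on 4 taxa: no homoplasy
        m = make_matrix("abcd", [[{0}, {0}, {1}, {1}],
                                 [{0}, {0}, {1}, {1}]])
        result = exhaustive_search(m)
        assert result.ci == 1.0


class TestConsensusAndSupport:
    def test_identical_trees_consensus_is_that_tree(self):
        t = PhyloTree.from_newick("((A,B),(C,D),E);")
        cons = strict_consensus([t.copy(), t.copy()], t.taxa)
        assert cons.topology_key(t.taxa) == t.topology_key(t.taxa)

    def test_disjoint_trees_give_star(self):
        a = PhyloTree.from_newick("((A,B),(C,D),E);")
        b = PhyloTree.from_newick("((A,C),(B,D),E);")
        cons = strict_consensus([a, b], a.taxa)
        assert cons.splits(a.taxa) == set()

    def test_split_set_is_intersection(self, rng):
        taxa = list("ABCDEFG")
        trees = [random_topology(taxa, rng).unroot() for _ in range(4)]
        cons = strict_consensus(trees, taxa)
        expected = set.intersection(*(t.splits(taxa) for t in trees))
        assert cons.splits(taxa) == expected

    def test_bootstrap_on_congruent_characters_is_100(self):
        cols = [[{0}, {0}, {1}, {1}, {1}]] * 12
        m = make_matrix("abcde", cols)
        records = bootstrap(m, n_reps=20, reps_per_search=1, seed=2)
        focal = [r for r in records if r.taxa in
                 ({"a", "b"}, {"c", "d", "e"})]
        assert focal and all(r.bootstrap == 100.0 for r in focal)

    def test_bootstrap_seeded_reproducible(self, small_matrix):
        a = bootstrap(small_matrix, n_reps=5, reps_per_search=1, seed=11)
        b = bootstrap(small_matrix, n_reps=5, reps_per_search=1, seed=11)
        assert [(r.mask, r.bootstrap) for r in a] \
            == [(r.mask, r.bootstrap) for r in b]


class TestBremer:
    def test_single_supporting_character_decay_one(self):
        # one binary character forcing {a,b}; nothing else informative
        cols = [[{0}, {0}, {1}, {1}, {1}]]
        m = make_matrix("abcde", cols)
        result = exhaustive_search(m)
        consensus = strict_consensus(result.mpt_set, m.taxa)
        [mask] = [s for s in consensus.splits(m.taxa)]
        assert bremer_decay(m, mask, result.length, m.taxa) == 1

    def test_matches_exhaustive_on_simulated_fixture(self):
        config = SimulationConfig(n_taxa=7, n_chars=40, seed=13,
                                  tree_depth=0.9, gamma=False)
        m = simulate_matrix(simulate_tree(config), config)
        result = exhaustive_search(m)
        consensus = strict_consensus(result.mpt_set, m.taxa)
        for mask in consensus.splits(m.taxa):
            d = bremer_decay(m, mask, result.length, m.taxa)
            # exhaustive reverse-constraint optimum, by definition
            best_without = min(
                tree_length(t, m) for t in enumerate_topologies(m.taxa)
                if mask not in t.splits(m.taxa))
            assert d == best_without - result.length
            assert d >= 1  # consensus splits are in every MPT
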