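"""Posterior summaries: burn-in, consensus, monophyly, Bayes factors."""

import math

import numpy as np
import pytest

from morphoclade.samples import Draw, TreeSample
from morphoclade.summary import (DEFAULT_ZANDER_TABLE, bayes_factor,
                                 discard_burnin, harmonic_mean_lnL,
                                 hypothesis_battery, majority_consensus,
                                 monophyly_pp, pool_samples, zander_correct)
from morphoclade.trees import PhyloTree

TAXA = ["A", "B", "C", "D", "E"]
AB = "((A:1,B:2):3,(C:1,D:1):2,E:1);"
AC = "((A:1,C:1):1,(B:1,D:1):1,E:1);"
CD = "((C:2,D:2):4,(A:1,B:1):2,E:1);"


def _sample(newicks, start=0):
    return TreeSample(draws=[
        Draw(cycle=start + i, tree=PhyloTree.from_newick(s), lnL=-1.0)
        for i, s in enumerate(newicks)])


class TestBurnin:
    def test_quarter_of_80k_leaves_60k(self):
        t = PhyloTree.from_newick(AB)
        sample = TreeSample(draws=[Draw(cycle=i, tree=t, lnL=-1.0)
                                   for i in range(80_000)])
        assert len(discard_burnin(sample, 0.25)) == 60_000

    def test_zero_fraction_is_identity(self):
        sample = _sample([AB, AC, CD])
        assert len(discard_burnin(sample, 0.0)) == 3

    def test_floor_rounding_on_odd_counts(self):
        sample = _sample([AB] * 7)
        assert len(discard_burnin(sample, 0.5)) == 4  # floor(3.5) removed


class TestConsensus:
    def test_unanimous_sample_returns_topology_with_pp_one(self):
        cons = majority_consensus(_sample([AB] * 5), TAXA)
        assert set(cons.support.values()) == {1.0}
        ref = PhyloTree.from_newick(AB)
        assert cons.tree.topology_key(TAXA) == ref.topology_key(TAXA)

    def test_six_of_ten_split_labelled_point_six(self):
        # AB-topology splits ({A,B} and {C,D}) occur in 6 of 10 trees
        cons = majority_consensus(_sample([AB] * 6 + [AC] * 4), TAXA)
        for mask in PhyloTree.from_newick(AB).splits(TAXA):
            assert cons.support[mask] == pytest.approx(0.6)

    def test_exact_half_split_excluded(self):
        cons = majority_consensus(_sample([AB] * 5 + [AC] * 5), TAXA)
        ab_splits = PhyloTree.from_newick(AB).splits(TAXA)
        ac_splits = PhyloTree.from_newick(AC).splits(TAXA)
        for mask in (ab_splits ^ ac_splits):
            assert mask not in cons.support

    def test_branch_lengths_average_over_supporting_trees(self):
        # {C,D} subtends length 2 in the first tree and 4 in the second
        cons = majority_consensus(_sample([AB, CD]), TAXA)
        nodes = cons.tree.splits(TAXA, with_nodes=True)
        cd_mask = (1 << TAXA.index("C")) | (1 << TAXA.index("D"))
        assert nodes[cd_mask].length == pytest.approx((2 + 4) / 2)

    def test_splits_are_mutually_compatible(self):
        # a scrambled sample still yields a tree (construction would raise
        # on incompatible splits)
        cons = majority_consensus(_sample([AB, AC, CD, AB, CD]), TAXA)
        cons.tree.validate()

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            majority_consensus(TreeSample(), TAXA)


class TestMonophyly:
    def test_all_but_outgroup_is_always_a_clade(self):
        test = monophyly_pp(_sample([AB, AC, CD]), {"A", "B", "C", "D"},
                            "E", taxon_order=TAXA)
        assert test.pp == 1.0

    def test_nine_of_ten_supporting_trees(self):
        test = monophyly_pp(_sample([AB] * 9 + [AC]), {"A", "B"}, "E",
                            taxon_order=TAXA)
        assert test.pp == pytest.approx(0.9)
        assert test.n_supporting == 9

    def test_branch_length_scaled_by_character_count(self):
        test = monophyly_pp(_sample([AB]), {"A", "B"}, "E",
                            taxon_order=TAXA, n_characters=100)
        assert test.branch_length_changes == pytest.approx(3.0 * 100)

    def test_wild_taxon_equivalent_to_pruned_test(self):
        """Declaring a taxon wild equals testing on trees with it pruned."""
        from morphoclade.summary import _prune_taxa

        sample = _sample([AB, AC, CD, AB])
        with_wild = monophyly_pp(sample, {"A", "B", "C"}, "E",
                                 taxon_order=TAXA, wild={"C"})
        order = [t for t in TAXA if t != "C"]
        full = (1 << len(order)) - 1
        mask = sum(1 << order.index(t) for t in ("A", "B"))
        norm = (full & ~mask) if mask & 1 else mask
        direct = sum(
            norm in _prune_taxa(draw.tree, {"C"}).splits(order)
            for draw in sample)
        assert direct == 3  # clade holds in the AB/CD topologies only
        assert with_wild.pp == pytest.approx(direct / 4)

    def test_outgroup_inside_clade_rejected(self):
        with pytest.raises(ValueError):
            monophyly_pp(_sample([AB]), {"A", "E"}, "E", taxon_order=TAXA)

    def test_unknown_taxon_rejected(self):
        with pytest.raises(ValueError, match="ZZ"):
            monophyly_pp(_sample([AB]), {"A", "ZZ"}, "E", taxon_order=TAXA)


class TestZander:
    def test_full_support_at_28_changes_is_credible(self):
        assert zander_correct(1.00, 28.2) == "credible_95"

    def test_half_support_never_credible(self):
        for length in (1.0, 20.0, 34.9, 35.0, 100.0):
            assert zander_correct(0.5, length) == "not_credible_95"

    def test_boundary_35_uses_uncorrected_cutoff(self):
        assert zander_correct(0.95, 35.0) == "credible_95"
        assert zander_correct(0.95, 34.999) == "not_credible_95"

    def test_short_branch_requires_table_threshold(self):
        # below 15 changes the default table demands PP >= 0.99
        assert zander_correct(0.985, 10.0) == "not_credible_95"
        assert zander_correct(0.99, 10.0) == "credible_95"
        # 0.96 fails everywhere below 35 under the default table
        for length in (5.0, 20.0, 30.0):
            assert zander_correct(0.96, length) == "not_credible_95"

    def test_non_monotone_table_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            zander_correct(0.99, 10.0, table=[(0.0, 0.97), (10.0, 0.99)])

    def test_default_table_is_monotone(self):
        lengths = [t[0] for t in DEFAULT_ZANDER_TABLE]
        cutoffs = [t[1] for t in DEFAULT_ZANDER_TABLE]
        assert lengths == sorted(lengths)
        assert cutoffs == sorted(cutoffs, reverse=True)


class TestHarmonicMean:
    def test_constant_lnL_returns_it(self):
        sample = TreeSample(draws=[
            Draw(cycle=i, tree=PhyloTree.from_newick(AB), lnL=-42.5)
            for i in range(4)])
        assert harmonic_mean_lnL(sample) == pytest.approx(-42.5, abs=1e-12)

    def test_two_point_example(self):
        # harmonic mean of {1, 1/3} is 1/2
        sample = TreeSample(draws=[
            Draw(cycle=0, tree=PhyloTree.from_newick(AB), lnL=math.log(1.0)),
            Draw(cycle=1, tree=PhyloTree.from_newick(AB),
                 lnL=math.log(1 / 3))])
        assert harmonic_mean_lnL(sample) == pytest.approx(math.log(0.5),
                                                          abs=1e-12)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(0)
        lnls = list(rng.normal(-100, 5, size=50))
        s1 = TreeSample(draws=[
            Draw(cycle=i, tree=PhyloTree.from_newick(AB), lnL=v)
            for i, v in enumerate(lnls)])
        s2 = TreeSample(draws=[
            Draw(cycle=i, tree=PhyloTree.from_newick(AB), lnL=v + 7.0)
            for i, v in enumerate(lnls)])
        assert harmonic_mean_lnL(s2) == pytest.approx(
            harmonic_mean_lnL(s1) + 7.0, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            harmonic_mean_lnL(TreeSample())


class TestBayesFactor:
    def test_gamma_vs_no_gamma_printed_example(self):
        cmp = bayes_factor(-12837.0, -11719.0)
        assert cmp.B == pytest.approx(1118.0)
        assert cmp.verdict == "strong"

    def test_equal_models_bare_mention(self):
        cmp = bayes_factor(-5.0, -5.0)
        assert cmp.B == 0.0
        assert cmp.verdict == "not worth more than a bare mention"

    def test_antisymmetry(self):
        assert bayes_factor(-10.0, -4.0).B == -bayes_factor(-4.0, -10.0).B

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor(float("nan"), 0.0)


class TestBattery:
    def test_fixed_clade_pp_one_and_absent_clade_upper_bound(self):
        sample = _sample([AB] * 10)
        df = hypothesis_battery(
            sample,
            [("ab", frozenset({"A", "B"})),
             ("ad", frozenset({"A", "D"}))],
            outgroup="E", taxon_order=TAXA, n_characters=10)
        ab = df[df.name == "ab"].iloc[0]
        ad = df[df.name == "ad"].iloc[0]
        assert ab.pp == 1.0
        assert ad.pp == 0.0
        assert ad.pp_display == "<0.1"

    def test_zero_count_display_matches_pool_size(self):
        sample = _sample([AB] * 125)
        df = hypothesis_battery(sample, [("ad", frozenset({"A", "D"}))],
                                outgroup="E", taxon_order=TAXA)
        assert df.iloc[0].pp_display == "<0.008"

    def test_pooling_concatenates_runs(self):
        a = _sample([AB] * 3)
        b = _sample([AC] * 2)
        pooled = pool_samples([a, b])
        assert len(pooled) == 5
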