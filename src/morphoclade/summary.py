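"""Posterior summaries: consensus trees, marginal-likelihood estimation,
Bayes factors, and monophyly hypothesis tests with branch-length-corrected
credibility.

Clade support is the posterior probability (PP): the fraction of
post-burnin sampled trees in which a taxon set is monophyletic after
rooting on the outgroup.  Because PP is known to be liberal at the short
branch lengths typical of morphological matrices (fewer than ~35 expected
changes), credibility verdicts pass through a pluggable monotone lookup
giving, for each branch length, the minimum PP accepted as >=95% credible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .samples import TreeSample
from .trees import PhyloTree, detach_subtree, tree_from_splits

__all__ = [
    "SplitTable", "ModelComparison", "MonophylyTest", "ConsensusTree",
    "discard_burnin", "pool_samples", "majority_consensus", "monophyly_pp",
    "zander_correct", "harmonic_mean_lnL", "bayes_factor",
    "hypothesis_battery", "DEFAULT_ZANDER_TABLE", "load_zander_table",
]


# ------------------------------------------------------------ basic pooling


def discard_burnin(sample: TreeSample, fraction: float) -> TreeSample:
    """Drop the first floor(fraction * n) draws of a run."""
    return sample.discard_burnin(fraction)


def pool_samples(samples) -> TreeSample:
    """Concatenate several (already post-burnin) runs into one pool."""
    if isinstance(samples, TreeSample):
        return samples
    draws = []
    offset = 0
    for s in samples:
        for d in s:
            draws.append(type(d)(cycle=offset + d.cycle, tree=d.tree,
                                 lnL=d.lnL, alpha=d.alpha))
        if s.draws:
            offset += s.draws[-1].cycle + 1
    return TreeSample(draws=draws, run_id="pooled")


# ------------------------------------------------------------- split tables


@dataclass
class SplitTable:
    """Bipartition bitmask -> posterior frequency, over ``taxon_order``."""

    taxon_order: list[str]
    frequencies: dict[int, float]
    n_samples: int
    mean_lengths: dict[int, float] = field(default_factory=dict)

    def frequency(self, mask: int) -> float:
        return self.frequencies.get(self.normalize(mask), 0.0)

    def normalize(self, mask: int) -> int:
        full = (1 << len(self.taxon_order)) - 1
        return (full & ~mask) if mask & 1 else mask

    def mask_of(self, taxon_set) -> int:
        index = {t: i for i, t in enumerate(self.taxon_order)}
        mask = 0
        for t in taxon_set:
            if t not in index:
                raise ValueError(f"unknown taxon {t!r}")
            mask |= 1 << index[t]
        return mask

    @classmethod
    def from_sample(cls, sample: TreeSample,
                    taxon_order: list[str]) -> "SplitTable":
        counts: dict[int, int] = {}
        length_sums: dict[int, float] = {}
        for draw in sample:
            for mask, node in draw.tree.splits(
                    taxon_order, with_nodes=True).items():
                counts[mask] = counts.get(mask, 0) + 1
                length_sums[mask] = length_sums.get(mask, 0.0) + node.length
        n = max(len(sample), 1)
        return cls(
            taxon_order=list(taxon_order),
            frequencies={m: c / n for m, c in counts.items()},
            n_samples=len(sample),
            mean_lengths={m: length_sums[m] / c for m, c in counts.items()},
        )


@dataclass
class ConsensusTree:
    tree: PhyloTree
    taxon_order: list[str]
    support: dict[int, float]  # split mask -> PP

    def to_newick(self) -> str:
        nodes = self.tree.splits(self.taxon_order, with_nodes=True)
        labels = {node: f"{self.support[mask]:.4f}"
                  for mask, node in nodes.items() if mask in self.support}
        return self.tree.to_newick(labels=labels)


def majority_consensus(samples, taxon_order: list[str]) -> ConsensusTree:
    """Majority-rule consensus: exactly the splits at frequency > 0.5
    (pairwise compatible by the majority property), labelled with their
    posterior frequency; branch lengths are means over the trees containing
    each split."""
    pool = pool_samples(samples)
    if not len(pool):
        raise ValueError("empty tree sample")
    table = SplitTable.from_sample(pool, taxon_order)
    majority = {m: table.mean_lengths[m]
                for m, f in table.frequencies.items() if f > 0.5}
    tree = tree_from_splits(taxon_order, majority)
    # pendant branch lengths: mean over all sampled trees
    pend_sums = {t: 0.0 for t in taxon_order}
    for draw in pool:
        for leaf in draw.tree.leaves():
            pend_sums[leaf.label] += leaf.length
    for leaf in tree.leaves():
        leaf.length = pend_sums[leaf.label] / len(pool)
    support = {m: table.frequencies[m] for m in majority}
    return ConsensusTree(tree=tree, taxon_order=list(taxon_order),
                         support=support)


# --------------------------------------------------------- monophyly tests


@dataclass
class MonophylyTest:
    name: str
    taxon_set: frozenset[str]
    pp: float
    n_supporting: int
    n_samples: int
    branch_length_changes: float | None  # expected changes on subtending edge
    verdict: str | None = None

    @property
    def pp_display(self) -> str:
        """Table-style PP; zero counts as a strict upper bound '<1/n'."""
        if self.n_supporting == 0:
            return f"<{1.0 / max(self.n_samples, 1):.6g}"
        return f"{self.pp:.6g}"


def _prune_taxa(tree: PhyloTree, labels: set[str]) -> PhyloTree:
    out = tree.copy()
    for label in labels:
        leaf = next(n for n in out.leaves() if n.label == label)
        if leaf.parent is None:
            raise ValueError("cannot prune the only remaining taxon")
        detach_subtree(out, leaf)
    return out


def monophyly_pp(samples, taxon_set, outgroup: str,
                 taxon_order: list[str] | None = None,
                 n_characters: int | None = None,
                 wild: set[str] | None = None,
                 name: str = "") -> MonophylyTest:
    """Posterior probability that ``taxon_set`` is a clade when trees are
    rooted on ``outgroup``; optional ``wild`` taxa are pruned before the
    test.  The branch length reported is the mean, over supporting trees,
    of the subtending edge length; multiplied by ``n_characters`` when
    given, so it reads in expected character changes."""
    pool = pool_samples(samples)
    wild = set(wild or ())
    taxon_set = frozenset(taxon_set) - wild
    if len(taxon_set) < 2:
        raise ValueError("monophyly test needs at least two taxa")
    if outgroup in taxon_set:
        raise ValueError("outgroup cannot be part of the tested clade")
    tips = set(pool.draws[0].tree.taxa) if pool.draws else set()
    unknown = (taxon_set | wild) - tips
    if unknown:
        raise ValueError(f"taxa not in the trees: {sorted(unknown)}")
    order = [t for t in (taxon_order or sorted(tips)) if t not in wild]
    target = 0
    index = {t: i for i, t in enumerate(order)}
    for t in taxon_set:
        target |= 1 << index[t]
    full = (1 << len(order)) - 1
    norm = (full & ~target) if target & 1 else target
    trivial = len(taxon_set) >= len(order) - 1
    n_support = 0
    length_sum = 0.0
    for draw in pool:
        tree = _prune_taxa(draw.tree, wild) if wild else draw.tree
        if trivial:
            n_support += 1
            out_leaf = next(n for n in tree.leaves() if n.label == outgroup)
            length_sum += out_leaf.length
            continue
        nodes = tree.splits(order, with_nodes=True)
        if norm in nodes:
            n_support += 1
            length_sum += nodes[norm].length
    n = max(len(pool), 1)
    mean_len = (length_sum / n_support) if n_support else None
    if mean_len is not None and n_characters is not None:
        mean_len *= n_characters
    return MonophylyTest(
        name=name or ",".join(sorted(taxon_set)),
        taxon_set=taxon_set, pp=n_support / n, n_supporting=n_support,
        n_samples=len(pool), branch_length_changes=mean_len)


# ----------------------------------------------- branch-length correction

# Approximate stand-in for a published correction table: minimum PP deemed
# >= 95% credible as a step function of clade branch length (in expected
# character changes).  Anchored conservatively; beyond 35 changes no
# correction applies (plain 0.95 cutoff).
DEFAULT_ZANDER_TABLE: list[tuple[float, float]] = [
    (0.0, 0.99),
    (15.0, 0.98),
    (25.0, 0.97),
]


def load_zander_table(path) -> list[tuple[float, float]]:
    """Read a correction table from TSV (columns branch_length, min_pp)."""
    df = pd.read_csv(path, sep="\t")
    return [(float(r.iloc[0]), float(r.iloc[1])) for _, r in df.iterrows()]


def zander_correct(pp: float, branch_length_changes: float,
                   table: list[tuple[float, float]] | None = None) -> str:
    """Credibility verdict for a clade PP, corrected for branch length.

    At >= 35 expected changes the uncorrected 0.95 cutoff applies; below,
    the clade is credible only if PP reaches the table's threshold for its
    branch length (step function, thresholds non-increasing in length).
    """
    if not 0.0 <= pp <= 1.0:
        raise ValueError("pp must be in [0, 1]")
    table = DEFAULT_ZANDER_TABLE if table is None else table
    lengths = [t[0] for t in table]
    cutoffs = [t[1] for t in table]
    if sorted(lengths) != lengths or any(
            b > a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("correction table must be monotone "
                         "(increasing lengths, non-increasing cutoffs)")
    if branch_length_changes >= 35.0:
        ok = pp >= 0.95
    else:
        threshold = cutoffs[0]
        for length, cut in table:
            if branch_length_changes >= length:
                threshold = cut
        ok = pp >= threshold
    return "credible_95" if ok else "not_credible_95"


# ------------------------------------------------------- model comparison


def harmonic_mean_lnL(sample: TreeSample) -> float:
    """ln of the harmonic mean of sampled likelihoods, in log space."""
    lnls = np.asarray(sample.lnLs, dtype=float)
    if lnls.size == 0:
        raise ValueError("empty sample")
    return float(-(logsumexp(-lnls) - math.log(lnls.size)))


@dataclass
class ModelComparison:
    two_lnL_a: float
    two_lnL_b: float
    B: float
    verdict: str


def bayes_factor(two_lnL_a: float, two_lnL_b: float) -> ModelComparison:
    """Bayes factor on the 2ln scale: B = 2lnL(b) - 2lnL(a), b the
    candidate; interpretive banding follows the conventional 2lnB scale
    (>10 strong)."""
    if not (math.isfinite(two_lnL_a) and math.isfinite(two_lnL_b)):
        raise ValueError("2lnL inputs must be finite")
    B = two_lnL_b - two_lnL_a
    a = abs(B)
    if a < 2.0:
        verdict = "not worth more than a bare mention"
    elif a < 6.0:
        verdict = "positive"
    elif a < 10.0:
        verdict = "substantial"
    else:
        verdict = "strong"
    return ModelComparison(two_lnL_a=two_lnL_a, two_lnL_b=two_lnL_b,
                           B=B, verdict=verdict)


# --------------------------------------------------------------- batteries


def hypothesis_battery(samples, hypotheses, outgroup: str,
                       taxon_order: list[str] | None = None,
                       n_characters: int | None = None,
                       zander_table=None) -> pd.DataFrame:
    """One monophyly test per named hypothesis.

    ``hypotheses``: iterable of (name, taxon_set) or (name, taxon_set,
    wild_set).  Zero-frequency clades are displayed as '<1/n_samples'.
    Returns a DataFrame with columns name, pp, pp_display, branch_length,
    verdict.
    """
    pool = pool_samples(samples)
    rows = []
    for hyp in hypotheses:
        name, taxa = hyp[0], hyp[1]
        wild = hyp[2] if len(hyp) > 2 else None
        test = monophyly_pp(pool, taxa, outgroup, taxon_order=taxon_order,
                            n_characters=n_characters, wild=wild, name=name)
        verdict = None
        if test.branch_length_changes is not None:
            verdict = zander_correct(test.pp, test.branch_length_changes,
                                     zander_table)
        rows.append({
            "name": name,
            "pp": test.pp,
            "pp_display": test.pp_display,
            "branch_length": test.branch_length_changes,
            "verdict": verdict,
        })
    return pd.DataFrame(rows)


def read_hypotheses_tsv(path) -> list[tuple]:
    """Hypotheses file: TSV with columns name, taxa (semicolon list) and
    optional wild (semicolon list)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        taxa = frozenset(str(row["taxa"]).split(";"))
        wild = None
        if "wild" in df.columns and isinstance(row.get("wild"), str) \
                and row["wild"]:
            wild = set(row["wild"].split(";"))
        out.append((row["name"], taxa, wild))
    return out
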