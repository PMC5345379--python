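"""Synthetic data: pure-birth trees, Mk(+G) character matrices conditioned
on variability, Brownian quantitative traits, and a metadata fixture shaped
like a real morphological study's character list (163 characters, 27 of
them quantitative, a stated ordered set and exclusion set).

Every generator is seeded and deterministic.  The matrix simulator uses the
same transition machinery as the likelihood engine, so the rejection step
(resampling constant characters) matches the Mkv conditioning exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coding import QuantitativeTable
from .matrix import CharacterMatrix, CharacterMeta
from .mk import gamma_rates, rate_matrix, transition_probs
from .trees import Node, PhyloTree

__all__ = [
    "SimulationConfig", "simulate_tree", "simulate_matrix",
    "simulate_quantitative", "table2_fixture",
    "TABLE2_STATE_COUNTS", "TABLE2_QUANTITATIVE", "TABLE2_ORDERED",
    "TABLE2_EXCLUDED",
]


@dataclass
class SimulationConfig:
    n_taxa: int = 20
    n_chars: int = 163
    k_weights: dict[int, float] = field(
        default_factory=lambda: {2: 0.74, 3: 0.19, 4: 0.04, 5: 0.02, 6: 0.01})
    prop_ordered: float = 0.08   # among multistate (k >= 3) characters
    gamma: bool = True
    alpha_true: float = 0.5
    tree_depth: float = 0.5      # root-to-tip expected changes per character
    variable_only: bool = True
    missing_rate: float = 0.0
    polymorphism_rate: float = 0.0
    drift_variance: float = 1.0  # Brownian rate for quantitative traits
    n_quantitative: int = 27
    seed: int = 0

    def __post_init__(self):
        for name in ("prop_ordered", "missing_rate", "polymorphism_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")


def simulate_tree(config: SimulationConfig, rng=None) -> PhyloTree:
    """Pure-birth (Yule) topology with branch lengths rescaled so the mean
    root-to-tip path equals ``tree_depth``; returned unrooted (degree-3
    root) for n >= 3."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_taxa
    labels = [f"t{i + 1}" for i in range(n)]
    if n == 2:
        root = Node(label=labels[0])
        root.add(Node(label=labels[1], length=config.tree_depth))
        return PhyloTree(root)
    root = Node()
    tips = [root.add(Node(label=None)) for _ in range(2)]
    while len(tips) < n:
        # exponential waiting time with rate = number of lineages
        dt = float(rng.exponential(1.0 / len(tips)))
        for tip in tips:
            tip.length += dt
        split = tips.pop(rng.integers(0, len(tips)))
        tips.extend(split.add(Node(label=None)) for _ in range(2))
    dt = float(rng.exponential(1.0 / len(tips)))
    for tip in tips:
        tip.length += dt
    perm = rng.permutation(n)
    for tip, j in zip(tips, perm):
        tip.label = labels[j]
    tree = PhyloTree(root)
    depth = _mean_depth(tree)
    if depth > 0:
        scale = config.tree_depth / depth
        for node in tree.edges():
            node.length *= scale
    return tree.unroot()


def _mean_depth(tree: PhyloTree) -> float:
    depths = []

    def walk(node, acc):
        acc += node.length
        if node.is_leaf:
            depths.append(acc)
        for c in node.children:
            walk(c, acc)

    walk(tree.root, -tree.root.length if tree.root.parent else 0.0)
    return float(np.mean(depths)) if depths else 0.0


def _evolve_column(tree: PhyloTree, k: int, ordered: bool, rate: float,
                   rng) -> dict[str, int]:
    Q = rate_matrix(k, ordered=ordered)
    states: dict[int, int] = {id(tree.root): int(rng.integers(0, k))}
    out: dict[str, int] = {}
    for node in tree.preorder():
        if node.parent is not None:
            P = transition_probs(Q, node.length, rate)
            parent_state = states[id(node.parent)]
            states[id(node)] = int(rng.choice(k, p=P[parent_state]
                                              / P[parent_state].sum()))
        if node.is_leaf or node.label is not None:
            out[node.label] = states[id(node)]
    return out


def simulate_matrix(tree: PhyloTree, config: SimulationConfig,
                    rng=None) -> CharacterMatrix:
    """Evolve ``n_chars`` discrete characters on ``tree`` under Mk(+G),
    optionally conditioned on variability by rejection, then inject missing
    cells and two-state polymorphism sets at the configured rates."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    taxa = tree.taxa
    ks = sorted(config.k_weights)
    kp = np.array([config.k_weights[k] for k in ks], dtype=float)
    kp /= kp.sum()
    columns = []
    meta = []
    for j in range(config.n_chars):
        k = int(ks[rng.choice(len(ks), p=kp)])
        ordered = bool(k >= 3 and rng.random() < config.prop_ordered)
        while True:
            rate = (float(rng.gamma(config.alpha_true,
                                    1.0 / config.alpha_true))
                    if config.gamma else 1.0)
            if rate <= 0:
                continue
            col = _evolve_column(tree, k, ordered, rate, rng)
            if not config.variable_only or len(set(col.values())) > 1:
                break
        cells = []
        for t in taxa:
            s = col[t]
            u = rng.random()
            if u < config.missing_rate:
                cells.append(frozenset(range(k)))
            elif u < config.missing_rate + config.polymorphism_rate and k >= 2:
                other = int(rng.integers(0, k - 1))
                other = other if other != s else k - 1
                cells.append(frozenset({s, other}))
            else:
                cells.append(frozenset({s}))
        columns.append(cells)
        meta.append(CharacterMeta(index=j + 1, ordered=ordered, k=k))
    cells_by_taxon = [[columns[j][i] for j in range(config.n_chars)]
                      for i in range(len(taxa))]
    return CharacterMatrix(taxa=taxa, cells=cells_by_taxon, char_meta=meta)


def simulate_quantitative(tree: PhyloTree, config: SimulationConfig,
                          rng=None) -> QuantitativeTable:
    """Brownian-drift trait values along the tree, one column per
    quantitative character."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    taxa = tree.taxa
    values: dict[int, list[float]] = {}
    for j in range(config.n_quantitative):
        node_vals = {id(tree.root): 0.0}
        out = {}
        for node in tree.preorder():
            if node.parent is not None:
                step = (float(rng.normal(
                    0.0, np.sqrt(config.drift_variance * node.length)))
                    if node.length > 0 else 0.0)
                node_vals[id(node)] = node_vals[id(node.parent)] + step
            if node.is_leaf or node.label is not None:
                out[node.label] = node_vals[id(node)]
        values[j + 1] = [out[t] for t in taxa]
    return QuantitativeTable(taxa=taxa, values=values)


# --------------------------------------------------------------------------
# Study-shaped metadata fixture: 163 characters, 27 quantitative (binary
# after coding), 13 ordered multistate, 4 excluded.  State counts follow
# the published character list (maximum printed state index + 1).

TABLE2_STATE_COUNTS = [
    2, 2, 2, 2, 2, 2, 2, 3, 3, 3, 2, 2, 2, 2, 2, 2, 2, 2, 5, 4,
    2, 2, 2, 2, 3, 2, 3, 3, 3, 2, 4, 3, 2, 2, 3, 2, 3, 2, 2, 2,
    2, 2, 2, 2, 2, 2, 3, 3, 2, 4, 4, 5, 2, 2, 2, 2, 3, 2, 2, 3,
    2, 2, 2, 2, 3, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 3, 2,
    2, 2, 2, 2, 3, 2, 2, 2, 2, 2, 2, 2, 2, 5, 2, 3, 2, 2, 2, 2,
    2, 6, 2, 2, 2, 2, 2, 3, 2, 3, 2, 2, 2, 2, 2, 2, 3, 2, 4, 2,
    2, 2, 4, 3, 2, 3, 2, 2, 2, 2, 2, 2, 3, 3, 2, 2, 2, 2, 3, 2,
    2, 3, 2, 2, 3, 2, 2, 2, 2, 2, 2, 3, 2, 4, 2, 2, 2, 3, 2, 2,
    3, 2, 2,
]
TABLE2_QUANTITATIVE = frozenset({
    2, 3, 4, 7, 12, 18, 40, 41, 42, 43, 58, 61, 62, 77, 78, 88, 93,
    106, 111, 112, 113, 114, 115, 116, 131, 151, 156,
})
TABLE2_ORDERED = frozenset({6, 9, 22, 27, 29, 37, 44, 60, 85, 123, 133,
                            145, 161})
TABLE2_EXCLUDED = frozenset({9, 34, 46, 162})


def table2_fixture() -> list[CharacterMeta]:
    """Character metadata mirroring the study's character list."""
    out = []
    for i, k in enumerate(TABLE2_STATE_COUNTS, start=1):
        out.append(CharacterMeta(
            index=i,
            kind="quantitative" if i in TABLE2_QUANTITATIVE else "qualitative",
            ordered=i in TABLE2_ORDERED,
            k=2 if i in TABLE2_QUANTITATIVE else k,
            included=i not in TABLE2_EXCLUDED,
        ))
    return out
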