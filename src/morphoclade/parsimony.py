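"""Maximum parsimony: Fitch/Sankoff scoring, heuristic search with random
stepwise addition and branch swapping, consistency index, strict consensus,
nonparametric bootstrap and Bremer (decay) indices.

Unordered characters are scored by the Fitch set algorithm; ordered
characters by Sankoff dynamic programming with linear cost |i-j|.
Ambiguity sets (polymorphism, missing data) are free to resolve to
whichever state minimises length.  The heuristic search follows the
classic two-phase recipe: random-order stepwise addition replicates, each
swapped to completion (TBR by default), retaining all equally short trees
up to a (auto-growing) maxtrees cap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .matrix import CharacterMatrix, CharacterMeta
from .trees import (Node, PhyloTree, attach_on_edge, detach_subtree,
                    enumerate_topologies, random_topology, tree_from_splits)

__all__ = [
    "ParsimonyResult", "SupportRecord", "ParsimonyEngine",
    "character_length", "tree_length", "min_steps", "heuristic_search",
    "exhaustive_search", "parsimony_informative_count", "strict_consensus",
    "bootstrap", "bremer_decay",
]

_INF = np.inf


# ----------------------------------------------------------------- scoring


class ParsimonyEngine:
    """Vectorised tree-length scorer for a fixed matrix (included
    characters only)."""

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        self.taxa = list(matrix.taxa)
        row = {t: i for i, t in enumerate(self.taxa)}
        self._row = row
        unordered_cols = []
        self.ordered: list[tuple[int, np.ndarray]] = []  # (k, costs (ntaxa,k))
        for meta in matrix.char_meta:
            if not meta.included or meta.k < 2:
                continue
            col = matrix.column(meta.index)
            if meta.ordered:
                leaf_cost = np.full((matrix.n_taxa, meta.k), _INF)
                for i, cell in enumerate(col):
                    for s in cell:
                        leaf_cost[i, s] = 0.0
                self.ordered.append((meta.k, leaf_cost))
            else:
                unordered_cols.append([
                    sum(1 << s for s in cell) for cell in col
                ])
        # (ntaxa, nchar) bitmask matrix for all unordered characters
        self.unordered = (np.array(unordered_cols, dtype=np.int64).T
                          if unordered_cols else
                          np.zeros((matrix.n_taxa, 0), dtype=np.int64))

    def length(self, tree: PhyloTree) -> int:
        return int(self._fitch(tree) + self._sankoff(tree))

    def _fitch(self, tree: PhyloTree) -> int:
        if self.unordered.shape[1] == 0:
            return 0
        sets: dict[int, np.ndarray] = {}
        steps = 0
        for node in tree.postorder():
            if node.is_leaf:
                sets[id(node)] = self.unordered[self._row[node.label]]
                continue
            acc = None
            for child in node.children:
                cs = sets.pop(id(child))
                if acc is None:
                    acc = cs
                    continue
                inter = acc & cs
                union = acc | cs
                empty = inter == 0
                steps += int(empty.sum())
                acc = np.where(empty, union, inter)
            sets[id(node)] = acc
        return steps

    def _sankoff(self, tree: PhyloTree) -> int:
        total = 0
        for k, leaf_cost in self.ordered:
            cmat = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
            cost: dict[int, np.ndarray] = {}
            for node in tree.postorder():
                if node.is_leaf:
                    cost[id(node)] = leaf_cost[self._row[node.label]]
                    continue
                acc = np.zeros(k)
                for child in node.children:
                    cc = cost.pop(id(child))
                    acc = acc + (cc[None, :] + cmat).min(axis=1)
                cost[id(node)] = acc
            total += int(cost[id(tree.root)].min())
        return total


def character_length(tree: PhyloTree, column, meta: CharacterMeta,
                     taxa: list[str] | None = None) -> int:
    """Minimum steps of one character on ``tree`` (Fitch or ordered
    Sankoff); ambiguity sets resolve freely, missing costs nothing."""
    taxa = taxa if taxa is not None else tree.taxa
    one = CharacterMatrix(
        taxa=list(taxa), cells=[[frozenset(c)] for c in column],
        char_meta=[CharacterMeta(index=1, ordered=meta.ordered, k=meta.k)])
    return ParsimonyEngine(one).length(tree)


def tree_length(tree: PhyloTree, matrix: CharacterMatrix) -> int:
    """Total steps over included characters."""
    return ParsimonyEngine(matrix).length(tree)


def min_steps(column, meta: CharacterMeta) -> int:
    """Minimum conceivable steps of a character on any tree.

    Unordered: (size of the smallest state set hitting every cell) - 1;
    ordered: the width of the narrowest state interval hitting every cell.
    Cells equal to the full state space (missing) never constrain.
    """
    k = meta.k
    full = frozenset(range(k))
    cells = [frozenset(c) for c in column if frozenset(c) != full]
    if not cells:
        return 0
    if meta.ordered:
        best = k - 1
        for a in range(k):
            for b in range(a, k):
                window = set(range(a, b + 1))
                if all(c & window for c in cells):
                    best = min(best, b - a)
                    break
        return best
    states = sorted(set().union(*cells))
    for size in range(1, len(states) + 1):
        for combo in itertools.combinations(states, size):
            s = set(combo)
            if all(c & s for c in cells):
                return size - 1
    return len(states) - 1


def parsimony_informative_count(matrix: CharacterMatrix) -> int:
    """Included characters with >= 2 states each unambiguously observed
    (singleton cells) in >= 2 taxa."""
    count = 0
    for meta in matrix.char_meta:
        if not meta.included:
            continue
        tallies: dict[int, int] = {}
        for cell in matrix.column(meta.index):
            if len(cell) == 1:
                s = next(iter(cell))
                tallies[s] = tallies.get(s, 0) + 1
        if sum(1 for c in tallies.values() if c >= 2) >= 2:
            count += 1
    return count


# ------------------------------------------------------------------ results


@dataclass
class ParsimonyResult:
    mpt_set: list[PhyloTree]
    length: int
    ci: float
    search_log: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.mpt_set)


@dataclass
class SupportRecord:
    mask: int
    taxa: frozenset[str]
    bootstrap: float | None = None  # percent
    decay: int | None = None


def ensemble_ci(matrix: CharacterMatrix, length: int) -> float:
    """Consistency index: sum of per-character minima / realised length."""
    m = sum(min_steps(matrix.column(meta.index), meta)
            for meta in matrix.char_meta if meta.included)
    return m / length if length else 1.0


# ------------------------------------------------------------------- search


def _zero_lengths(tree: PhyloTree) -> PhyloTree:
    for node in tree.edges():
        node.length = 0.0
    return tree


def _random_addition(matrix: CharacterMatrix, engine: ParsimonyEngine,
                     rng) -> PhyloTree:
    """Random-order stepwise addition: greedy best insertion edge."""
    order = list(rng.permutation(matrix.n_taxa))
    taxa = [matrix.taxa[i] for i in order]
    root = Node()
    for t in taxa[:3]:
        root.add(Node(label=t))
    tree = PhyloTree(root)
    present = taxa[:3]
    for t in taxa[3:]:
        present.append(t)
        sub = (engine if len(present) == matrix.n_taxa
               else ParsimonyEngine(matrix.subset_taxa(present)))
        best_len, best_edges = None, []
        for i in range(tree.n_edges):
            work = tree.copy()
            attach_on_edge(work, work.edges()[i], Node(label=t))
            partial = sub.length(work)
            if best_len is None or partial < best_len:
                best_len, best_edges = partial, [i]
            elif partial == best_len:
                best_edges.append(i)
        choice = best_edges[rng.integers(0, len(best_edges))]
        attach_on_edge(tree, tree.edges()[choice], Node(label=t))
    return tree


def _spr_neighbors(tree: PhyloTree, tbr: bool = False):
    """All SPR (optionally TBR: rerooted-subtree) rearrangements."""
    nodes = [n for n in tree.postorder() if n.parent is not None]
    n_leaves = len(tree.leaves())
    for i, _ in enumerate(nodes):
        work = tree.copy()
        wnodes = [n for n in work.postorder() if n.parent is not None]
        x = wnodes[i]
        sub_leaves = sum(1 for n in _iter_subtree(x) if n.is_leaf)
        if n_leaves - sub_leaves < 3:
            continue
        detach_subtree(work, x)
        variants = [x] if not tbr else _rerootings(x)
        for variant in variants:
            for j in range(work.n_edges):
                cand = work.copy()
                vcopy = _copy_subtree(variant)
                attach_on_edge(cand, cand.edges()[j], vcopy)
                cand.unroot()
                yield cand


def _iter_subtree(node):
    stack = [node]
    while stack:
        cur = stack.pop()
        yield cur
        stack.extend(cur.children)


def _copy_subtree(node: Node) -> Node:
    out = Node(label=node.label, length=node.length)
    for c in node.children:
        out.add(_copy_subtree(c))
    return out


def _rerootings(sub_root: Node) -> list[Node]:
    """The pruned subtree re-hung from each of its internal edges (the TBR
    reconnection choices on the pruned side)."""
    variants = [sub_root]
    internal_edges = [n for n in _iter_subtree(sub_root)
                      if n is not sub_root and n.children]
    for idx in range(len(internal_edges)):
        work = _copy_subtree(sub_root)
        wedges = [n for n in _iter_subtree(work)
                  if n is not work and n.children]
        edge = wedges[idx]
        # new hang point on the edge above `edge`
        parent = edge.parent
        parent.remove(edge)
        new_root = Node()
        new_root.add(edge)
        # re-hang the old upper part below the new root
        path = []
        node = parent
        while node is not None:
            path.append(node)
            node = node.parent
        for upper, lower in zip(path[1:], path[:-1]):
            upper.children.remove(lower)
        for upper, lower in zip(path[1:], path[:-1]):
            lower.children.append(upper)
            upper.parent = lower
        new_root.add(parent)
        parent.parent = new_root
        for n in list(_iter_subtree(new_root)):
            _splice_degree2(new_root, n)
        variants.append(new_root)
    return variants


def _splice_degree2(root: Node, node: Node) -> None:
    if node is root or not node.children or len(node.children) != 1:
        return
    child = node.children[0]
    parent = node.parent
    if parent is None:
        return
    parent.children[parent.children.index(node)] = child
    child.parent = parent
    node.children = []


def heuristic_search(matrix: CharacterMatrix, reps: int = 10,
                     swapper: str = "tbr", maxtrees: int = 100,
                     seed: int = 0, auto_increase: bool = True,
                     maxtrees_cap: int = 10_000,
                     score=None) -> ParsimonyResult:
    """Random-addition + branch-swapping heuristic search.

    Per replicate: a random-order stepwise-addition tree is swapped to
    completion (every retained tree's full neighborhood examined),
    retaining all equally short trees up to ``maxtrees`` (grown by 100
    when full, if auto_increase).  ``score`` overrides the objective
    (used by reverse-constraint decay searches).
    """
    if matrix.n_taxa < 4:
        raise ValueError("parsimony search requires >= 4 taxa")
    engine = ParsimonyEngine(matrix)
    taxon_order = list(matrix.taxa)
    score = score or (lambda t: engine.length(t))
    rng = np.random.default_rng(seed)
    best_len: float = _INF
    pool: dict[frozenset, PhyloTree] = {}
    log = {"replicates": reps, "swapper": swapper, "maxtrees_events": 0,
           "swap_rounds": 0}

    def consider(tree: PhyloTree, length) -> bool:
        nonlocal best_len, maxtrees
        if length > best_len:
            return False
        key = tree.topology_key(taxon_order)
        if length < best_len:
            best_len = length
            pool.clear()
            pool[key] = tree
            return True
        if key in pool:
            return False
        if len(pool) >= maxtrees:
            if auto_increase and maxtrees < maxtrees_cap:
                maxtrees += 100
                log["maxtrees_events"] += 1
            else:
                return False
        pool[key] = tree
        return True

    neighbor_fns = {
        "nni": lambda t: _spr_neighbors(t, tbr=False),  # superset of NNI
        "spr": lambda t: _spr_neighbors(t, tbr=False),
        "tbr": lambda t: _spr_neighbors(t, tbr=True),
    }
    if swapper not in neighbor_fns:
        raise ValueError(f"unknown swapper {swapper!r}")
    neighbors = neighbor_fns[swapper]

    for _ in range(max(reps, 1)):
        start = _zero_lengths(_random_addition(matrix, engine, rng))
        start_len = score(start)
        consider(start, start_len)
        # swap to completion over the retained pool
        examined: set[frozenset] = set()
        while True:
            frontier = [k for k in pool if k not in examined]
            if not frontier:
                break
            log["swap_rounds"] += 1
            progress = False
            for key in frontier:
                if key not in pool:
                    continue
                examined.add(key)
                tree = pool[key]
                for cand in neighbors(tree):
                    if consider(_zero_lengths(cand), score(cand)):
                        progress = True
                if best_len < _INF and key not in pool:
                    break
            if not progress and not [k for k in pool if k not in examined]:
                break
    if not np.isfinite(best_len):
        raise ValueError("search found no admissible tree")
    mpts = list(pool.values())
    length = int(best_len)
    return ParsimonyResult(
        mpt_set=mpts, length=length,
        ci=ensemble_ci(matrix, length), search_log=log)


def exhaustive_search(matrix: CharacterMatrix, score=None) -> ParsimonyResult:
    """Score every unrooted topology (practical for <= 8 or 9 taxa)."""
    engine = ParsimonyEngine(matrix)
    score = score or (lambda t: engine.length(t))
    taxon_order = list(matrix.taxa)
    best_len = _INF
    pool: dict[frozenset, PhyloTree] = {}
    for tree in enumerate_topologies(taxon_order):
        length = score(tree)
        if length < best_len:
            best_len = length
            pool = {tree.topology_key(taxon_order): tree}
        elif length == best_len:
            pool.setdefault(tree.topology_key(taxon_order), tree)
    length = int(best_len)
    return ParsimonyResult(mpt_set=list(pool.values()), length=length,
                           ci=ensemble_ci(matrix, length),
                           search_log={"exhaustive": True})


# ----------------------------------------------------------------- support


def strict_consensus(trees: list[PhyloTree],
                     taxon_order: list[str]) -> PhyloTree:
    """Tree containing exactly the splits present in every input tree."""
    if not trees:
        raise ValueError("strict consensus of an empty tree set")
    common = trees[0].splits(taxon_order)
    for tree in trees[1:]:
        common &= tree.splits(taxon_order)
    return tree_from_splits(taxon_order, common)


def bootstrap(matrix: CharacterMatrix, n_reps: int = 100,
              reps_per_search: int = 10, swapper: str = "tbr",
              maxtrees: int = 1000, seed: int = 0) -> list[SupportRecord]:
    """Nonparametric bootstrap: resample included characters with
    replacement, re-search, and score each split by the percentage of
    replicates whose MPT strict consensus contains it."""
    base = matrix.drop_excluded()
    taxon_order = list(matrix.taxa)
    rng = np.random.default_rng(seed)
    counts: dict[int, int] = {}
    for _ in range(n_reps):
        picks = rng.integers(0, base.n_char, size=base.n_char)
        meta = []
        for new_idx, j in enumerate(picks):
            m = base.char_meta[j]
            meta.append(CharacterMeta(index=new_idx + 1, kind=m.kind,
                                      ordered=m.ordered, k=m.k))
        cells = [[row[j] for j in picks] for row in base.cells]
        resampled = CharacterMatrix(taxa=taxon_order, cells=cells,
                                    char_meta=meta)
        result = heuristic_search(resampled, reps=reps_per_search,
                                  swapper=swapper, maxtrees=maxtrees,
                                  seed=int(rng.integers(0, 2**31)))
        consensus = strict_consensus(result.mpt_set, taxon_order)
        for mask in consensus.splits(taxon_order):
            counts[mask] = counts.get(mask, 0) + 1
    index = {i: t for i, t in enumerate(taxon_order)}
    records = []
    for mask, c in sorted(counts.items(), key=lambda kv: -kv[1]):
        taxa = frozenset(index[i] for i in range(len(taxon_order))
                         if mask >> i & 1)
        records.append(SupportRecord(mask=mask, taxa=taxa,
                                     bootstrap=100.0 * c / n_reps))
    return records


def bremer_decay(matrix: CharacterMatrix, split_mask: int, mpt_length: int,
                 taxon_order: list[str] | None = None,
                 reps: int = 10, swapper: str = "tbr", seed: int = 0,
                 exhaustive_limit: int = 8) -> int:
    """Decay index: extra steps of the shortest tree *lacking* the split.

    For small problems every topology is evaluated; otherwise a
    reverse-constraint heuristic search treats trees containing the split
    as inadmissible.
    """
    taxon_order = taxon_order or list(matrix.taxa)
    engine = ParsimonyEngine(matrix)
    full = (1 << len(taxon_order)) - 1
    norm = (full & ~split_mask) if split_mask & 1 else split_mask

    def anti_score(tree: PhyloTree):
        if norm in tree.splits(taxon_order):
            return _INF
        return engine.length(tree)

    if matrix.n_taxa <= exhaustive_limit:
        best = _INF
        for tree in enumerate_topologies(taxon_order):
            s = anti_score(tree)
            if s < best:
                best = s
    else:
        result = heuristic_search(matrix, reps=reps, swapper=swapper,
                                  seed=seed, score=anti_score)
        best = result.length
    if best is _INF:
        raise ValueError("no tree lacking the split was found")
    return int(best - mpt_length)
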