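"""Phylogenetic tree container and topology operations.

Trees are stored rooted for traversal, but most analyses here treat them as
unrooted: an unrooted binary tree over n >= 3 taxa is normalised to a root
node of degree three (2n-3 edges, one branch length each, in expected
character changes per character).  Newick parsing goes through dendropy;
serialisation is direct.
"""

from __future__ import annotations

import io
from typing import Iterator

import dendropy

__all__ = ["Node", "PhyloTree"]


class Node:
    __slots__ = ("parent", "children", "length", "label")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.length = length  # branch length to parent
        self.label = label

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None


class PhyloTree:
    """Bifurcating tree with branch lengths and optional outgroup marker."""

    def __init__(self, root: Node, outgroup: str | None = None):
        self.root = root
        self.outgroup = outgroup

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )

        def convert(dnode) -> Node:
            label = dnode.taxon.label if dnode.taxon is not None else None
            node = Node(label=label, length=float(dnode.edge.length or 0.0))
            for child in dnode.child_nodes():
                node.add(convert(child))
            return node

        return cls(convert(dtree.seed_node))

    def to_newick(self, lengths: bool = True, labels: dict | None = None) -> str:
        """Serialise; ``labels`` optionally maps internal Node -> support label."""

        def fmt(node: Node) -> str:
            if node.is_leaf:
                out = _quote(node.label or "")
            else:
                out = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if labels is not None and node in labels:
                    out += str(labels[node])
            if lengths and node.parent is not None:
                out += f":{node.length:.10g}"
            return out

        return fmt(self.root) + ";"

    # ------------------------------------------------------------- traversal

    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        out.reverse()
        return out

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        # a labelled root with children occurs only in the 2-taxon
        # single-edge representation; it counts as a terminal
        return [n for n in self.postorder()
                if n.is_leaf or n.label is not None]

    @property
    def taxa(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def edges(self) -> list[Node]:
        """Every non-root node identifies the edge to its parent."""
        return [n for n in self.postorder() if n.parent is not None]

    @property
    def n_edges(self) -> int:
        return len(self.edges())

    def total_length(self) -> float:
        return sum(n.length for n in self.edges())

    def copy(self) -> "PhyloTree":
        def dup(node: Node) -> Node:
            out = Node(label=node.label, length=node.length)
            for child in node.children:
                out.add(dup(child))
            return out

        return PhyloTree(dup(self.root), outgroup=self.outgroup)

    def validate(self) -> None:
        taxa = self.taxa
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon labels in tree")
        for node in self.edges():
            if not (node.length >= 0.0) or node.length != node.length:
                raise ValueError(f"invalid branch length {node.length!r}")

    # ----------------------------------------------------------- bipartitions

    def splits(self, taxon_order: list[str], nontrivial_only: bool = True,
               with_nodes: bool = False):
        """Bipartitions as bitmasks over ``taxon_order`` (matrix row order).

        Each split is normalised to the side *not* containing taxon 0, so a
        bitmask never has bit 0 set.  Trivial splits (single taxon / all but
        one) are omitted unless requested.  With ``with_nodes`` returns a
        dict mask -> Node (the child end of the subtending edge).
        """
        index = {t: i for i, t in enumerate(taxon_order)}
        n = len(taxon_order)
        full = (1 << n) - 1
        masks: dict[Node, int] = {}
        result: dict[int, Node] = {}
        for node in self.postorder():
            if node.is_leaf:
                masks[node] = 1 << index[node.label]
            else:
                masks[node] = 0
                for c in node.children:
                    masks[node] |= masks[c]
            if node.parent is None:
                continue
            mask = masks[node]
            if mask & 1:
                mask = full & ~mask
            size = mask.bit_count()
            if nontrivial_only and (size < 2 or size > n - 2):
                continue
            if mask not in result:
                result[mask] = node
        return result if with_nodes else set(result)

    def topology_key(self, taxon_order: list[str]) -> frozenset:
        """Hashable unrooted-topology identifier (set of nontrivial splits)."""
        return frozenset(self.splits(taxon_order))

    # ------------------------------------------------------------- unrooting

    def unroot(self) -> "PhyloTree":
        """Normalise in place to a degree-3 root (n>=3); returns self."""
        while len(self.root.children) == 2 and not all(
            c.is_leaf for c in self.root.children
        ):
            a, b = self.root.children
            keep, lift = (a, b) if not a.is_leaf else (b, a)
            lift.length += keep.length
            keep.parent = None
            keep.children.append(lift)
            lift.parent = keep
            keep.length = 0.0
            self.root = keep
        return self

    def rooted_on(self, outgroup: str) -> "PhyloTree":
        """Copy rooted on the pendant edge of ``outgroup``."""
        tree = self.copy()
        target = next(n for n in tree.leaves() if n.label == outgroup)
        edge_len = target.length
        old_parent = target.parent
        if old_parent is None:
            return tree
        # reverse the parent chain so old_parent becomes the hang point;
        # the edge between path[i] and path[i+1] (stored on path[i]) moves
        # to path[i+1] when the chain flips
        path = []
        node = old_parent
        while node is not None:
            path.append(node)
            node = node.parent
        lengths = [n.length for n in path]
        for upper, lower in zip(path[1:], path[:-1]):
            upper.children.remove(lower)
        for i, (upper, lower) in enumerate(zip(path[1:], path[:-1])):
            lower.children.append(upper)
            upper.parent = lower
            upper.length = lengths[i]
        old_parent.parent = None
        old_parent.children.remove(target)
        root = Node()
        root.add(target)
        target.length = edge_len / 2.0
        root.add(old_parent)
        old_parent.length = edge_len / 2.0
        # the former root is now a degree-2 internal node: splice it out
        out = PhyloTree(root, outgroup=outgroup)
        for node in out.postorder():
            if node is not root and node.children and len(node.children) == 1:
                _suppress_unifurcations(node)
        return out


def canonicalize_root(tree: PhyloTree, ref_taxon: str) -> PhyloTree:
    """Re-hang the rooted *representation* at the internal node adjacent to
    ``ref_taxon``, in place, without changing the unrooted tree.

    With every internal node of degree 3 this is a pure relabelling of
    parent/child directions; it makes the representation a deterministic
    function of the unrooted tree, which MCMC proposals rely on for
    reversibility.
    """
    leaf = next(n for n in tree.postorder() if n.label == ref_taxon)
    hub = leaf.parent
    if hub is None or hub is tree.root:
        return tree
    path = []
    node = hub
    while node is not None:
        path.append(node)
        node = node.parent
    lengths = [n.length for n in path]
    for upper, lower in zip(path[1:], path[:-1]):
        upper.children.remove(lower)
    for i, (upper, lower) in enumerate(zip(path[1:], path[:-1])):
        lower.children.append(upper)
        upper.parent = lower
        upper.length = lengths[i]
    hub.parent = None
    hub.length = 0.0
    tree.root = hub
    return tree


def _suppress_unifurcations(node: Node) -> None:
    while len(node.children) == 1:
        child = node.children[0]
        child.length += node.length
        parent = node.parent
        if parent is None:
            return
        parent.children[parent.children.index(node)] = child
        child.parent = parent
        node.children = []
        node = parent


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]{}/\\,;:=*'\"`<>"):
        return "'" + label.replace("'", "''") + "'"
    return label


# --------------------------------------------------------------- construction


def random_topology(taxa: list[str], rng) -> PhyloTree:
    """Uniformly distributed unrooted binary topology via sequential edge
    insertion (each labelled topology arises from exactly one insertion
    sequence).  Branch lengths are zero."""
    if len(taxa) < 3:
        if len(taxa) == 1:
            return PhyloTree(Node(label=taxa[0]))
        root = Node(label=taxa[0])
        root.add(Node(label=taxa[1]))
        return PhyloTree(root)
    root = Node()
    for t in taxa[:3]:
        root.add(Node(label=t))
    tree = PhyloTree(root)
    for t in taxa[3:]:
        edge = tree.edges()[rng.integers(0, tree.n_edges)]
        attach_on_edge(tree, edge, Node(label=t))
    return tree


def attach_on_edge(tree: PhyloTree, edge_child: Node, subtree: Node,
                   split_at: float = 0.5) -> Node:
    """Insert a new node on the edge above ``edge_child`` and hang
    ``subtree`` from it; returns the new node.  ``split_at`` is the fraction
    of the edge length assigned below the new node."""
    parent = edge_child.parent
    mid = Node(length=edge_child.length * (1.0 - split_at))
    parent.children[parent.children.index(edge_child)] = mid
    mid.parent = parent
    edge_child.length = edge_child.length * split_at
    mid.add(edge_child)
    mid.add(subtree)
    return mid


def detach_subtree(tree: PhyloTree, node: Node) -> float | None:
    """Remove ``node`` (and its subtree) from the tree, splicing out the
    degree-2 node left behind and renormalising the root if needed.

    Returns the length of the edge created by merging the two edges around
    the removed attachment point, or None when no merge happened (the
    remaining tree has only two leaves, or the root kept degree >= 3).
    """
    parent = node.parent
    parent.remove(node)
    if parent.parent is None:
        if len(parent.children) == 2:
            a, b = parent.children
            if a.is_leaf and b.is_leaf:
                return None
            old_lengths = a.length + b.length
            tree.unroot()
            return old_lengths
        return None
    if len(parent.children) == 1:
        sibling = parent.children[0]
        merged = sibling.length + parent.length
        grand = parent.parent
        grand.children[grand.children.index(parent)] = sibling
        sibling.parent = grand
        sibling.length = merged
        parent.children = []
        return merged
    return None


def enumerate_topologies(taxa: list[str]) -> Iterator[PhyloTree]:
    """All (2n-5)!! unrooted binary topologies (practical for n <= 8)."""
    if len(taxa) < 3:
        yield random_topology(taxa, None)
        return

    def build(tree: PhyloTree, remaining: list[str]) -> Iterator[PhyloTree]:
        if not remaining:
            yield tree.copy()
            return
        t, rest = remaining[0], remaining[1:]
        for i in range(tree.n_edges):
            work = tree.copy()
            attach_on_edge(work, work.edges()[i], Node(label=t))
            yield from build(work, rest)

    root = Node()
    for t in taxa[:3]:
        root.add(Node(label=t))
    yield from build(PhyloTree(root), list(taxa[3:]))


def tree_from_splits(taxon_order: list[str],
                     split_masks: dict[int, float] | set) -> PhyloTree:
    """Build the (possibly multifurcating) tree containing exactly the given
    pairwise-compatible nontrivial splits.

    Each mask is the split side not containing taxon 0 (see
    :meth:`PhyloTree.splits`); ``split_masks`` may map mask -> branch length.
    Raises ValueError on incompatible (non-nested, non-disjoint) splits.
    """
    n = len(taxon_order)
    if not isinstance(split_masks, dict):
        split_masks = {m: 0.0 for m in split_masks}
    masks = sorted(split_masks, key=lambda m: m.bit_count())
    for i, a in enumerate(masks):
        for b in masks[i + 1:]:
            inter = a & b
            if inter and inter != a and inter != b:
                raise ValueError("incompatible splits")
    nodes = {m: Node(length=split_masks[m]) for m in masks}

    def smallest_container(mask: int, candidates) -> int | None:
        best = None
        for c in candidates:
            if c != mask and (mask & ~c) == 0:
                if best is None or c.bit_count() < best.bit_count():
                    best = c
        return best

    root = Node()
    for m in masks:
        container = smallest_container(m, masks)
        (nodes[container] if container is not None else root).add(nodes[m])
    for i, t in enumerate(taxon_order):
        leaf_mask = 1 << i
        container = smallest_container(leaf_mask, masks) if i else None
        (nodes[container] if container is not None else root).add(
            Node(label=t))
    return PhyloTree(root)
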