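"""Independent reference implementations used to check the package.

Everything here is deliberately naive: likelihoods by full enumeration of
internal-state assignments, parsimony by exhaustive evaluation, counting
by direct scans.  None of it shares code paths with the implementations
under test beyond the rate-matrix definition.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm

from morphoclade.trees import PhyloTree


def brute_rate_matrix(k: int, ordered: bool) -> np.ndarray:
    Q = np.zeros((k, k))
    if ordered:
        for i in range(k - 1):
            Q[i, i + 1] = Q[i + 1, i] = 1.0
    else:
        Q[:] = 1.0
        np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q / -np.mean(np.diag(Q))


def brute_loglik(tree: PhyloTree, column, k: int, ordered: bool,
                 rates) -> float:
    """Log-likelihood by summation over all internal-state assignments,
    using scipy's expm for transition probabilities.  ``column`` is a list
    of state sets in the tree's leaf order."""
    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_leaf]
    leaf_state = {id(n): column[i] for i, n in enumerate(tree.leaves())}
    Q = brute_rate_matrix(k, ordered)
    total = 0.0
    for r in rates:
        P = {id(n): expm(Q * n.length * r)
             for n in nodes if n.parent is not None}
        lik = 0.0
        for assign in itertools.product(range(k), repeat=len(internals)):
            amap = {id(n): s for n, s in zip(internals, assign)}
            p = 1.0 / k
            for n in nodes:
                if n.parent is None:
                    continue
                sp = amap[id(n.parent)]
                if n.is_leaf:
                    p *= sum(P[id(n)][sp, s] for s in leaf_state[id(n)])
                else:
                    p *= P[id(n)][sp, amap[id(n)]]
            lik += p
        total += lik / len(rates)
    return float(np.log(total))


def brute_char_length(tree: PhyloTree, column, k: int,
                      ordered: bool) -> int:
    """Parsimony steps by minimisation over all internal assignments and
    all resolutions of ambiguous leaves."""
    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_leaf]
    leaves = tree.leaves()
    leaf_sets = [sorted(column[i]) for i in range(len(leaves))]
    best = None
    for leaf_choice in itertools.product(*leaf_sets):
        state = {id(n): s for n, s in zip(leaves, leaf_choice)}
        for assign in itertools.product(range(k), repeat=len(internals)):
            state.update({id(n): s for n, s in zip(internals, assign)})
            steps = 0
            for n in nodes:
                if n.parent is None:
                    continue
                a, b = state[id(n)], state[id(n.parent)]
                steps += abs(a - b) if ordered else int(a != b)
            if best is None or steps < best:
                best = steps
    return best
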