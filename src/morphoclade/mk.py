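"""Mk / Mkv likelihood engine for discrete morphological characters.

The Mk model is a k-state symmetric Markov process (equal rates between all
state pairs, uniform stationary distribution); its "v" variant conditions
each character's likelihood on being variable, correcting for the
ascertainment bias of morphological matrices in which constant characters
are never recorded.  Ordered multistate characters use an adjacent-states
(birth-death chain) rate matrix under the same normalisation of one
expected change per unit branch length.  Rate variation across characters
is a discrete-gamma mixture with mean-one category rates.

The per-character correction divides the likelihood by ``1 - c`` where
``c = sum_s Pr(all scored taxa show state s)`` (taxa with missing data are
marginalised out), averaged over gamma categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .matrix import CharacterMatrix, CharacterMeta
from .trees import PhyloTree

__all__ = [
    "MkModelSpec", "PatternLikelihood", "gamma_rates", "rate_matrix",
    "transition_probs", "character_loglik", "matrix_loglik",
    "LikelihoodEngine",
]


@dataclass
class MkModelSpec:
    """Likelihood configuration: gamma rate variation (ncat categories,
    shape alpha) and the conditioning mode ('all' = plain Mk, 'variable' =
    Mkv ascertainment correction)."""

    gamma: bool = False
    ncat: int = 4
    alpha: float = 1.0
    conditioning: str = "all"  # or "variable"
    gamma_mode: str = "mean"   # or "median" category representatives

    def __post_init__(self):
        if self.ncat < 1:
            raise ValueError("ncat must be >= 1")
        if self.alpha <= 0:
            raise ValueError("gamma shape alpha must be > 0")
        if self.conditioning not in ("all", "variable"):
            raise ValueError(f"unknown conditioning {self.conditioning!r}")
        if self.gamma_mode not in ("mean", "median"):
            raise ValueError(f"unknown gamma_mode {self.gamma_mode!r}")

    def rates(self, alpha: float | None = None) -> np.ndarray:
        if not self.gamma:
            return np.ones(1)
        return gamma_rates(alpha if alpha is not None else self.alpha,
                           self.ncat, self.gamma_mode)


@dataclass
class PatternLikelihood:
    """Per-character likelihood pieces: raw lnL, constant-pattern mass c,
    and the variable-conditioned lnL (equal to lnL - ln(1-c))."""

    lnL: float
    constant_mass: float
    corrected_lnL: float


def gamma_rates(alpha: float, ncat: int, mode: str = "mean") -> np.ndarray:
    """Equal-probability discrete-gamma category rates with mean one."""
    if ncat == 1:
        return np.ones(1)
    if mode == "median":
        quantiles = (2 * np.arange(ncat) + 1) / (2 * ncat)
        rates = gamma_dist.ppf(quantiles, a=alpha, scale=1.0 / alpha)
        return rates / rates.mean()
    bounds = gamma_dist.ppf(np.arange(ncat + 1) / ncat, a=alpha,
                            scale=1.0 / alpha)
    upper = gammainc(alpha + 1.0, alpha * bounds[1:])
    lower = gammainc(alpha + 1.0, alpha * bounds[:-1])
    rates = ncat * (upper - lower)
    return rates / rates.mean()


def rate_matrix(k: int, ordered: bool = False) -> np.ndarray:
    """Symmetric k-state rate matrix scaled to one expected change per unit
    branch length under the uniform stationary distribution."""
    if k < 2:
        raise ValueError("rate_matrix requires k >= 2")
    if ordered:
        Q = np.zeros((k, k))
        for i in range(k - 1):
            Q[i, i + 1] = Q[i + 1, i] = 1.0
    else:
        Q = np.ones((k, k)) - np.eye(k)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -np.mean(np.diag(Q))  # uniform stationary distribution
    return Q / mean_rate


def transition_probs(Q: np.ndarray, nu: float, r: float = 1.0) -> np.ndarray:
    """P(nu*r) = exp(Q * nu * r) via symmetric eigendecomposition."""
    if nu < 0:
        raise ValueError("branch length nu must be >= 0")
    if r <= 0:
        raise ValueError("rate multiplier r must be > 0")
    w, V = eigh(Q)
    P = (V * np.exp(w * nu * r)) @ V.T
    return np.clip(P, 0.0, 1.0)


# --------------------------------------------------------------------------
# vectorised pruning engine

try:  # optional JIT: the kernel is plain nested loops either way
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@_njit(cache=False)
def _prune_kernel(leafpart, leaf_row, is_leaf, child_flat, child_ptr,
                  lengths, V, w, rates):
    """Felsenstein pruning over one character block.

    Nodes are in postorder (root last).  ``leafpart`` is (ntaxa, ncol, k);
    transition matrices come from the spectral form P(t) = V e^{wt} V^T.
    Returns (site likelihoods, per-column log scaling) with uniform root
    frequencies.
    """
    n_nodes = is_leaf.shape[0]
    ncol = leafpart.shape[1]
    k = leafpart.shape[2]
    ncat = rates.shape[0]
    part = np.empty((n_nodes, ncol, ncat, k))
    logscale = np.zeros(ncol)
    P = np.empty((k, k))
    for i in range(n_nodes):
        if is_leaf[i]:
            row = leaf_row[i]
            for c in range(ncol):
                for a in range(ncat):
                    for s in range(k):
                        part[i, c, a, s] = leafpart[row, c, s]
            continue
        for c in range(ncol):
            for a in range(ncat):
                for s in range(k):
                    part[i, c, a, s] = 1.0
        for ci in range(child_ptr[i], child_ptr[i + 1]):
            child = child_flat[ci]
            t = lengths[child]
            for a in range(ncat):
                tr = t * rates[a]
                expw = np.empty(k)
                for m in range(k):
                    expw[m] = np.exp(w[m] * tr)
                for s in range(k):
                    for j in range(k):
                        acc = 0.0
                        for m in range(k):
                            acc += V[s, m] * expw[m] * V[j, m]
                        P[s, j] = acc if acc > 0.0 else 0.0
                for c in range(ncol):
                    for s in range(k):
                        msg = 0.0
                        for j in range(k):
                            msg += P[s, j] * part[child, c, a, j]
                        part[i, c, a, s] *= msg
        if i != n_nodes - 1:  # rescale away from the root
            for c in range(ncol):
                mx = 0.0
                for a in range(ncat):
                    for s in range(k):
                        if part[i, c, a, s] > mx:
                            mx = part[i, c, a, s]
                if mx > 0.0:
                    logscale[c] += np.log(mx)
                    inv = 1.0 / mx
                    for a in range(ncat):
                        for s in range(k):
                            part[i, c, a, s] *= inv
    site = np.zeros(ncol)
    root = n_nodes - 1
    for c in range(ncol):
        tot = 0.0
        for a in range(ncat):
            for s in range(k):
                tot += part[root, c, a, s]
        site[c] = tot / (ncat * k)
    return site, logscale


class _Block:
    """Characters sharing (k, ordered), stacked for one kernel call.

    After the real columns the block carries constant-pattern
    pseudo-columns (one per distinct missing-data mask and state) from
    which the Mkv ascertainment term is read off in the same traversal.
    """

    def __init__(self, k: int, ordered: bool):
        self.k = k
        self.ordered = ordered
        w, V = eigh(rate_matrix(k, ordered=ordered))
        self.eigw = np.ascontiguousarray(w)
        self.eigv = np.ascontiguousarray(V)
        self.char_indices: list[int] = []
        self.cells: list[list[frozenset]] = []
        self.leaf = None
        self.n_real = 0
        self.pseudo_slices: list[tuple[int, int]] = []

    def finalize(self, n_taxa: int):
        k = self.k
        self.n_real = len(self.char_indices)
        full = frozenset(range(k))
        masks = [tuple(c == full for c in col) for col in self.cells]
        pseudo: list[tuple[tuple, int]] = []
        pseudo_of_mask: dict[tuple, tuple[int, int]] = {}
        for mask in dict.fromkeys(masks):
            start = self.n_real + len(pseudo)
            pseudo_of_mask[mask] = (start, start + k)
            pseudo.extend((mask, s) for s in range(k))
        self.pseudo_slices = [pseudo_of_mask[m] for m in masks]
        ncol = self.n_real + len(pseudo)
        self.leaf = np.zeros((n_taxa, ncol, k))
        for j, col in enumerate(self.cells):
            for i, cell in enumerate(col):
                for s in cell:
                    self.leaf[i, j, s] = 1.0
        for pj, (mask, s) in enumerate(pseudo):
            j = self.n_real + pj
            for i in range(n_taxa):
                if mask[i]:
                    self.leaf[i, j, :] = 1.0
                else:
                    self.leaf[i, j, s] = 1.0
        self.cells = []


class LikelihoodEngine:
    """Pruning likelihood for a fixed matrix under an Mk(v)(+G) model.

    Characters are grouped by (state count, ordered flag) into stacked
    blocks at construction; :meth:`loglik` then evaluates any tree over
    the matrix taxa.  Underflow is handled by per-character rescaling of
    partial likelihoods.
    """

    def __init__(self, matrix: CharacterMatrix, spec: MkModelSpec):
        self.matrix = matrix
        self.spec = spec
        self.taxon_row = {t: i for i, t in enumerate(matrix.taxa)}
        self.blocks: dict[tuple[int, bool], _Block] = {}
        for meta in matrix.char_meta:
            if not meta.included or meta.k < 2:
                continue  # invariant single-state characters carry no signal
            ordered = bool(meta.ordered and meta.k > 2)  # k=2: same model
            key = (meta.k, ordered)
            block = self.blocks.setdefault(key, _Block(*key))
            block.char_indices.append(meta.index)
            block.cells.append(matrix.column(meta.index))
        for block in self.blocks.values():
            block.finalize(matrix.n_taxa)
        self._rates_cache: tuple[float, np.ndarray] | None = None

    # -- core evaluation ---------------------------------------------------

    def _rates(self, alpha: float | None) -> np.ndarray:
        if not self.spec.gamma:
            return np.ones(1)
        a = self.spec.alpha if alpha is None else alpha
        if self._rates_cache is not None and self._rates_cache[0] == a:
            return self._rates_cache[1]
        rates = np.ascontiguousarray(
            gamma_rates(a, self.spec.ncat, self.spec.gamma_mode))
        self._rates_cache = (a, rates)
        return rates

    def _traversal(self, tree: PhyloTree):
        post = tree.postorder()
        index = {id(n): i for i, n in enumerate(post)}
        n = len(post)
        is_leaf = np.zeros(n, dtype=np.bool_)
        leaf_row = np.zeros(n, dtype=np.int64)
        lengths = np.zeros(n)
        child_lists = []
        for i, node in enumerate(post):
            is_leaf[i] = node.is_leaf
            lengths[i] = node.length
            if node.is_leaf:
                leaf_row[i] = self.taxon_row[node.label]
            child_lists.append([index[id(c)] for c in node.children])
        child_ptr = np.zeros(n + 1, dtype=np.int64)
        for i, cl in enumerate(child_lists):
            child_ptr[i + 1] = child_ptr[i] + len(cl)
        child_flat = np.array(
            [c for cl in child_lists for c in cl] or [0], dtype=np.int64)
        return is_leaf, leaf_row, child_flat, child_ptr, lengths

    def _block_results(self, tree: PhyloTree, alpha: float | None):
        """Yields (block, lnL over real columns, constant mass c) tuples."""
        rates = self._rates(alpha)
        trav = self._traversal(tree)
        for block in self.blocks.values():
            site, logscale = _prune_kernel(
                block.leaf, trav[1], trav[0], trav[2], trav[3], trav[4],
                block.eigv, block.eigw, rates)
            lnL = np.log(np.maximum(site, 1e-300)) + logscale
            lik = np.exp(lnL)
            n = block.n_real
            cmass = np.array([lik[a:b].sum() for (a, b) in block.pseudo_slices])
            yield block, lnL[:n], cmass

    def per_character(self, tree: PhyloTree,
                      alpha: float | None = None) -> dict[int, PatternLikelihood]:
        """PatternLikelihood per included character (1-based keys)."""
        out: dict[int, PatternLikelihood] = {}
        for block, lnL, cmass in self._block_results(tree, alpha):
            for pos, idx in enumerate(block.char_indices):
                c = float(cmass[pos])
                if self.spec.conditioning == "variable":
                    if c >= 1.0 - 1e-12:
                        raise ValueError(
                            f"character {idx}: cannot condition on "
                            "variability (constant-pattern mass is 1; "
                            "column has no scored taxa)")
                    corrected = lnL[pos] - np.log1p(-c)
                else:
                    corrected = lnL[pos]
                out[idx] = PatternLikelihood(
                    lnL=float(lnL[pos]), constant_mass=c,
                    corrected_lnL=float(corrected))
        return out

    def loglik(self, tree: PhyloTree, alpha: float | None = None) -> float:
        """Total (corrected) log-likelihood over included characters."""
        total = 0.0
        for block, lnL, cmass in self._block_results(tree, alpha):
            if self.spec.conditioning == "variable":
                if np.any(cmass >= 1.0 - 1e-12):
                    bad = block.char_indices[int(np.argmax(cmass))]
                    raise ValueError(
                        f"character {bad}: cannot condition on variability "
                        "(column has no scored taxa)")
                total += float((lnL - np.log1p(-cmass)).sum())
            else:
                total += float(lnL.sum())
        return total


def character_loglik(tree: PhyloTree, column, meta: CharacterMeta,
                     spec: MkModelSpec, taxa: list[str] | None = None
                     ) -> PatternLikelihood:
    """Likelihood of a single character column on ``tree``.

    ``column`` is a list of state sets in ``taxa`` order (default: the
    tree's leaf order).
    """
    taxa = taxa if taxa is not None else [n.label for n in tree.leaves()]
    if len(column) != len(taxa):
        raise ValueError("column length does not match taxa")
    cells = [[frozenset(c)] for c in column]
    one = CharacterMatrix(taxa=list(taxa), cells=cells, char_meta=[
        CharacterMeta(index=1, ordered=meta.ordered, k=meta.k,
                      kind=meta.kind, included=True)])
    engine = LikelihoodEngine(one, spec)
    if not engine.blocks:
        raise ValueError("character has k < 2; no likelihood defined")
    return engine.per_character(tree)[1]


def matrix_loglik(tree: PhyloTree, matrix: CharacterMatrix,
                  spec: MkModelSpec) -> float:
    """Sum of corrected per-character log-likelihoods over included
    characters; excluded characters contribute exactly zero."""
    return LikelihoodEngine(matrix, spec).loglik(tree)
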