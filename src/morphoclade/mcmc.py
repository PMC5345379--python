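"""Bayesian MCMC over tree topology, branch lengths and gamma shape.

A single cold Metropolis-Hastings chain per run, with cross-run topological
convergence measured by the average standard deviation of split frequencies
(ASDSF).  Priors: uniform over labelled unrooted topologies, i.i.d.
exponential branch lengths, exponential gamma-shape prior.  Proposals: NNI
and SPR on the topology, log-scale multipliers on one branch length or on
the gamma shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .matrix import CharacterMatrix
from .mk import LikelihoodEngine, MkModelSpec
from .samples import Draw, TreeSample
from .trees import (PhyloTree, attach_on_edge, canonicalize_root,
                    detach_subtree, random_topology)

__all__ = ["McmcConfig", "run_chain", "asdsf", "run_analysis",
           "expected_draw_count"]


def expected_draw_count(cycles: int, sample_every: int) -> int:
    """Number of draws a chain records: one per completed ``sample_every``
    cycles (a zero-cycle run records just the start state)."""
    if cycles == 0:
        return 1
    return cycles // sample_every


@dataclass
class McmcConfig:
    cycles: int = 100_000
    sample_every: int = 100
    n_runs: int = 4
    burnin_fraction: float = 0.25
    seed: int = 0
    seeds: list[int] | None = None  # explicit per-run seeds
    # proposal weights
    w_nni: float = 0.4
    w_spr: float = 0.1
    w_brlen: float = 0.4
    w_shape: float = 0.1
    # priors
    brlen_prior_mean: float = 0.1
    shape_prior_mean: float = 1.0
    # tuning
    brlen_window: float = 2.0 * math.log(2.0)
    shape_window: float = 2.0 * math.log(2.0)
    # convergence
    asdsf_threshold: float = 0.01
    asdsf_min_freq: float = 0.10
    # diagnostics / testing
    prior_only: bool = False

    def __post_init__(self):
        if self.cycles > 0 and not self.cycles >= self.sample_every >= 1:
            raise ValueError("need cycles >= sample_every >= 1")
        if not 0.0 <= self.burnin_fraction < 1.0:
            raise ValueError("burnin_fraction must be in [0, 1)")
        weights = (self.w_nni, self.w_spr, self.w_brlen, self.w_shape)
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise ValueError("proposal weights must be non-negative, not all zero")

    def run_seeds(self) -> list[int]:
        if self.seeds is not None:
            return list(self.seeds)
        return [(self.seed + 7919 * k) % (2**31) for k in range(self.n_runs)]


@dataclass
class ChainLog:
    run_id: str
    proposed: dict = field(default_factory=dict)
    accepted: dict = field(default_factory=dict)

    def record(self, move: str, ok: bool) -> None:
        self.proposed[move] = self.proposed.get(move, 0) + 1
        if ok:
            self.accepted[move] = self.accepted.get(move, 0) + 1

    def acceptance_rates(self) -> dict:
        return {
            m: self.accepted.get(m, 0) / n
            for m, n in self.proposed.items() if n
        }


# --------------------------------------------------------------- proposals


def _propose_nni(tree: PhyloTree, rng) -> bool:
    internal = [n for n in tree.edges() if not n.is_leaf]
    if not internal:
        return False
    v = internal[rng.integers(0, len(internal))]
    u = v.parent
    siblings = [c for c in u.children if c is not v]
    s = siblings[rng.integers(0, len(siblings))]
    c = v.children[rng.integers(0, len(v.children))]
    v.remove(c)
    u.remove(s)
    v.add(s)
    u.add(c)
    return True


def _propose_spr(tree: PhyloTree, rng):
    """Returns log Hastings ratio, or None when the draw was illegal."""
    nodes = [n for n in tree.postorder() if n.parent is not None]
    x = nodes[rng.integers(0, len(nodes))]
    n_leaves = len(tree.leaves())
    sub_leaves = sum(1 for n in _subtree_nodes(x) if n.is_leaf)
    if n_leaves - sub_leaves < 3:
        return None
    merged = detach_subtree(tree, x)
    if merged is None or merged <= 0:
        merged = 1e-12
    edges = tree.edges()
    target = edges[rng.integers(0, len(edges))]
    target_len = max(target.length, 1e-12)
    attach_on_edge(tree, target, x, split_at=float(rng.random()))
    tree.unroot()
    return math.log(target_len) - math.log(merged)


def _subtree_nodes(node):
    stack = [node]
    while stack:
        cur = stack.pop()
        yield cur
        stack.extend(cur.children)


def _log_prior(tree: PhyloTree, alpha, config: McmcConfig,
               gamma: bool) -> float:
    mu = config.brlen_prior_mean
    lp = sum(-n.length / mu - math.log(mu) for n in tree.edges())
    if gamma and alpha is not None:
        ma = config.shape_prior_mean
        lp += -alpha / ma - math.log(ma)
    return lp


# ------------------------------------------------------------------- chain


def run_chain(matrix: CharacterMatrix, spec: MkModelSpec,
              config: McmcConfig, run_id: str = "run1",
              seed: int | None = None) -> tuple[TreeSample, ChainLog]:
    """One Metropolis-Hastings chain; deterministic given the seed.

    Draws are recorded after every ``sample_every`` cycles (one proposal
    per cycle), so ``cycles // sample_every`` draws in total; a zero-cycle
    run records the random start state only.
    """
    if matrix.n_taxa < 4:
        raise ValueError("MCMC requires at least 4 taxa")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    engine = None if config.prior_only else LikelihoodEngine(matrix, spec)

    ref_taxon = matrix.taxa[0]
    tree = random_topology(list(matrix.taxa), rng).unroot()
    canonicalize_root(tree, ref_taxon)
    for node in tree.edges():
        node.length = float(rng.exponential(config.brlen_prior_mean))
    alpha = (float(rng.exponential(config.shape_prior_mean))
             if spec.gamma else None)

    def loglik(t, a):
        return 0.0 if engine is None else engine.loglik(t, a)

    lnL = loglik(tree, alpha)
    lnP = _log_prior(tree, alpha, config, spec.gamma)
    log = ChainLog(run_id=run_id)
    draws: list[Draw] = []
    if config.cycles == 0:
        draws.append(Draw(cycle=0, tree=tree.copy(), lnL=lnL, alpha=alpha))

    moves = ["nni", "spr", "brlen", "shape"]
    weights = np.array([config.w_nni, config.w_spr, config.w_brlen,
                        config.w_shape if spec.gamma else 0.0])
    weights = weights / weights.sum()

    for cycle in range(1, config.cycles + 1):
        move = moves[rng.choice(4, p=weights)]
        log_hastings = 0.0
        new_alpha = alpha
        if move in ("nni", "spr"):
            cand = tree.copy()
            if move == "nni":
                ok = _propose_nni(cand, rng)
            else:
                lh = _propose_spr(cand, rng)
                ok = lh is not None
                log_hastings = lh or 0.0
            if ok:
                # keep the rooted representation a deterministic function
                # of the unrooted tree (reversibility of the moves)
                canonicalize_root(cand, ref_taxon)
            if not ok:
                log.record(move, False)
                if cycle % config.sample_every == 0:
                    draws.append(Draw(cycle=cycle, tree=tree.copy(),
                                      lnL=lnL, alpha=alpha))
                continue
        elif move == "brlen":
            cand = tree.copy()
            edges = cand.edges()
            edge = edges[rng.integers(0, len(edges))]
            factor = math.exp(config.brlen_window * (rng.random() - 0.5))
            edge.length = max(edge.length, 1e-12) * factor
            log_hastings = math.log(factor)
        else:  # shape
            cand = tree
            factor = math.exp(config.shape_window * (rng.random() - 0.5))
            new_alpha = alpha * factor
            log_hastings = math.log(factor)

        cand_lnL = loglik(cand, new_alpha)
        cand_lnP = _log_prior(cand, new_alpha, config, spec.gamma)
        log_ratio = (cand_lnL + cand_lnP) - (lnL + lnP) + log_hastings
        accept = log_ratio >= 0 or rng.random() < math.exp(log_ratio)
        log.record(move, accept)
        if accept:
            if cand is not tree:
                tree = cand
            alpha = new_alpha
            lnL, lnP = cand_lnL, cand_lnP
        if cycle % config.sample_every == 0:
            draws.append(Draw(cycle=cycle, tree=tree.copy(), lnL=lnL,
                              alpha=alpha))
    return TreeSample(draws=draws, run_id=run_id), log


# ------------------------------------------------------------- diagnostics


def split_frequencies(sample: TreeSample, taxon_order: list[str]) -> dict[int, float]:
    counts: dict[int, int] = {}
    n = len(sample)
    for draw in sample:
        for mask in draw.tree.splits(taxon_order):
            counts[mask] = counts.get(mask, 0) + 1
    return {m: c / n for m, c in counts.items()}


def asdsf(samples: list[TreeSample], taxon_order: list[str],
          min_freq: float = 0.10) -> float:
    """Average standard deviation of split frequencies across runs.

    Considers every nontrivial bipartition whose frequency reaches
    ``min_freq`` in at least one run; returns the mean across-run sample
    standard deviation (0.0 when no split qualifies).  Callers pass
    post-burnin samples.
    """
    if len(samples) < 2:
        raise ValueError("ASDSF requires at least two runs")
    freqs = [split_frequencies(s, taxon_order) for s in samples]
    qualifying = {m for f in freqs for m, v in f.items() if v >= min_freq}
    if not qualifying:
        return 0.0
    sds = [
        float(np.std([f.get(m, 0.0) for f in freqs], ddof=1))
        for m in qualifying
    ]
    return float(np.mean(sds))


def run_analysis(matrix: CharacterMatrix, spec: MkModelSpec,
                 config: McmcConfig):
    """n_runs independent chains plus a convergence/selection report.

    The report carries each run's harmonic-mean lnL and the final ASDSF
    over post-burnin samples, and flags the run with the highest
    harmonic-mean lnL (the run-selection rule for downstream inference).
    """
    from .summary import harmonic_mean_lnL

    samples: list[TreeSample] = []
    logs = []
    for k, run_seed in enumerate(config.run_seeds()):
        sample, log = run_chain(matrix, spec, config,
                                run_id=f"run{k + 1}", seed=run_seed)
        samples.append(sample)
        logs.append(log)
    post = [s.discard_burnin(config.burnin_fraction) for s in samples]
    hms = [harmonic_mean_lnL(s) for s in post]
    final_asdsf = (asdsf(post, list(matrix.taxa), config.asdsf_min_freq)
                   if len(post) > 1 else float("nan"))
    best = int(np.argmax(hms))
    report = {
        "runs": [
            {"run_id": s.run_id, "harmonic_mean_lnL": hm,
             "acceptance_rates": log.acceptance_rates()}
            for s, hm, log in zip(samples, hms, logs)
        ],
        "asdsf": final_asdsf,
        "converged": bool(final_asdsf <= config.asdsf_threshold)
        if final_asdsf == final_asdsf else False,
        "selected_run": samples[best].run_id,
    }
    return samples, report
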