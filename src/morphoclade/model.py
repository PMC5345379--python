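"""Model/Results interface over the pipeline.

Two fit-able models over a :class:`~morphoclade.matrix.CharacterMatrix`:

* :class:`BayesianMkv` — posterior sampling of topology, branch lengths
  and gamma shape under Mk(v)(+G); ``fit()`` returns a
  :class:`BayesianMkvResults` carrying the per-run samples, convergence
  diagnostics, harmonic-mean marginal likelihoods, and methods for
  consensus trees and monophyly tests.
* :class:`MaxParsimony` — heuristic most-parsimonious-tree search;
  ``fit()`` returns a :class:`ParsimonyFitResults` with tree length,
  consistency index, strict consensus, bootstrap and Bremer support.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import parsimony as pars
from . import summary as summ
from .matrix import CharacterMatrix
from .mcmc import McmcConfig, run_analysis
from .mk import LikelihoodEngine, MkModelSpec
from .nexus import read_nexus
from .samples import TreeSample

__all__ = ["BayesianMkv", "BayesianMkvResults", "MaxParsimony",
           "ParsimonyFitResults"]


class BayesianMkv:
    """Bayesian Mkv(+G) tree model for a discrete character matrix."""

    def __init__(self, matrix: CharacterMatrix,
                 spec: MkModelSpec | None = None):
        self.matrix = matrix
        self.spec = spec or MkModelSpec(gamma=True, ncat=4,
                                        conditioning="variable")

    @classmethod
    def from_nexus(cls, path, **spec_kwargs) -> "BayesianMkv":
        spec = MkModelSpec(gamma=True, ncat=4, conditioning="variable")
        if spec_kwargs:
            spec = replace(spec, **spec_kwargs)
        return cls(read_nexus(path), spec)

    def loglik(self, tree, alpha: float | None = None) -> float:
        return LikelihoodEngine(self.matrix, self.spec).loglik(tree, alpha)

    def fit(self, config: McmcConfig | None = None,
            **config_kwargs) -> "BayesianMkvResults":
        config = config or McmcConfig(**config_kwargs)
        samples, report = run_analysis(self.matrix, self.spec, config)
        return BayesianMkvResults(self, config, samples, report)


class BayesianMkvResults:
    def __init__(self, model: BayesianMkv, config: McmcConfig,
                 samples: list[TreeSample], report: dict):
        self.model = model
        self.config = config
        self.samples = samples
        self.report = report

    @property
    def taxon_order(self) -> list[str]:
        return list(self.model.matrix.taxa)

    @property
    def post_burnin(self) -> list[TreeSample]:
        return [s.discard_burnin(self.config.burnin_fraction)
                for s in self.samples]

    @property
    def pooled(self) -> TreeSample:
        return summ.pool_samples(self.post_burnin)

    @property
    def asdsf(self) -> float:
        return self.report["asdsf"]

    @property
    def harmonic_mean_lnL(self) -> float:
        """Harmonic-mean lnL of the selected (best) run."""
        best = self.report["selected_run"]
        for run in self.report["runs"]:
            if run["run_id"] == best:
                return run["harmonic_mean_lnL"]
        raise KeyError(best)

    def alpha_posterior(self) -> np.ndarray:
        return np.array([d.alpha for d in self.pooled if d.alpha is not None])

    def consensus(self) -> summ.ConsensusTree:
        return summ.majority_consensus(self.pooled, self.taxon_order)

    def split_table(self) -> summ.SplitTable:
        return summ.SplitTable.from_sample(self.pooled, self.taxon_order)

    def test_monophyly(self, taxon_set, outgroup: str, wild=None,
                       name: str = "") -> summ.MonophylyTest:
        n_inc = self.model.matrix.n_included
        test = summ.monophyly_pp(self.pooled, taxon_set, outgroup,
                                 taxon_order=self.taxon_order,
                                 n_characters=n_inc, wild=wild, name=name)
        if test.branch_length_changes is not None:
            test.verdict = summ.zander_correct(test.pp,
                                               test.branch_length_changes)
        return test

    def hypothesis_battery(self, hypotheses, outgroup: str):
        return summ.hypothesis_battery(
            self.pooled, hypotheses, outgroup,
            taxon_order=self.taxon_order,
            n_characters=self.model.matrix.n_included)

    def summary(self) -> str:
        lines = [
            "Bayesian Mkv model fit",
            "======================",
            f"taxa: {self.model.matrix.n_taxa}   "
            f"characters: {self.model.matrix.n_included} included "
            f"of {self.model.matrix.n_char}",
            f"model: Mk{'v' if self.model.spec.conditioning == 'variable' else ''}"
            + (f"+G({self.model.spec.ncat})" if self.model.spec.gamma else ""),
            f"runs: {len(self.samples)}   cycles: {self.config.cycles}   "
            f"sampled every {self.config.sample_every}",
            f"burn-in fraction: {self.config.burnin_fraction}",
            f"ASDSF (post burn-in): {self.asdsf:.4f}"
            f"   converged(<{self.config.asdsf_threshold}): "
            f"{self.report['converged']}",
        ]
        for run in self.report["runs"]:
            mark = " *" if run["run_id"] == self.report["selected_run"] else ""
            lines.append(f"  {run['run_id']}: harmonic-mean lnL = "
                         f"{run['harmonic_mean_lnL']:.3f}{mark}")
        alphas = self.alpha_posterior()
        if alphas.size:
            lines.append(f"gamma shape alpha: posterior mean "
                         f"{alphas.mean():.3f} "
                         f"(95% CI {np.percentile(alphas, 2.5):.3f}"
                         f"-{np.percentile(alphas, 97.5):.3f})")
        return "\n".join(lines)


class MaxParsimony:
    """Maximum-parsimony analysis of a discrete character matrix."""

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix

    @classmethod
    def from_nexus(cls, path) -> "MaxParsimony":
        return cls(read_nexus(path))

    def fit(self, reps: int = 10, swapper: str = "tbr",
            maxtrees: int = 100, seed: int = 0,
            exhaustive: bool = False) -> "ParsimonyFitResults":
        if exhaustive:
            result = pars.exhaustive_search(self.matrix)
        else:
            result = pars.heuristic_search(self.matrix, reps=reps,
                                           swapper=swapper,
                                           maxtrees=maxtrees, seed=seed)
        return ParsimonyFitResults(self, result, seed=seed, swapper=swapper)


class ParsimonyFitResults:
    def __init__(self, model: MaxParsimony, result: pars.ParsimonyResult,
                 seed: int = 0, swapper: str = "tbr"):
        self.model = model
        self.result = result
        self.seed = seed
        self.swapper = swapper

    @property
    def length(self) -> int:
        return self.result.length

    @property
    def ci(self) -> float:
        return self.result.ci

    @property
    def mpts(self):
        return self.result.mpt_set

    @property
    def taxon_order(self) -> list[str]:
        return list(self.model.matrix.taxa)

    def strict_consensus(self):
        return pars.strict_consensus(self.mpts, self.taxon_order)

    def informative_count(self) -> int:
        return pars.parsimony_informative_count(self.model.matrix)

    def bootstrap(self, n_reps: int = 100, reps_per_search: int = 10,
                  maxtrees: int = 1000, seed: int | None = None):
        return pars.bootstrap(self.model.matrix, n_reps=n_reps,
                              reps_per_search=reps_per_search,
                              swapper=self.swapper, maxtrees=maxtrees,
                              seed=self.seed if seed is None else seed)

    def bremer(self, split_mask: int, **kwargs) -> int:
        consensus = self.strict_consensus()
        table = consensus.splits(self.taxon_order)
        full = (1 << len(self.taxon_order)) - 1
        norm = (full & ~split_mask) if split_mask & 1 else split_mask
        if norm not in table:
            raise ValueError("split absent from the strict consensus")
        return pars.bremer_decay(self.model.matrix, norm, self.length,
                                 self.taxon_order, **kwargs)

    def summary(self) -> str:
        lines = [
            "Maximum parsimony fit",
            "=====================",
            f"taxa: {self.model.matrix.n_taxa}   included characters: "
            f"{self.model.matrix.n_included}",
            f"parsimony-informative characters: {self.informative_count()}",
            f"most parsimonious trees: {self.result.n_trees} of length "
            f"{self.length} steps",
            f"ensemble CI: {self.ci:.3f}",
            f"search: {self.result.search_log}",
        ]
        return "\n".join(lines)
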