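"""Posterior tree samples and their on-disk representation.

A :class:`TreeSample` holds ordered MCMC draws — (tree, log-likelihood,
gamma shape) triples keyed by cycle number.  On disk a sample is a pair of
tab-separated text files, MrBayes-style: ``<prefix>.t`` with one Newick tree
per cycle and ``<prefix>.p`` with the parameter trace (header
``cycle\\tlnL\\talpha``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .trees import PhyloTree

__all__ = ["Draw", "TreeSample", "read_tree_sample", "write_tree_sample"]


@dataclass
class Draw:
    cycle: int
    tree: PhyloTree
    lnL: float
    alpha: float | None = None


@dataclass
class TreeSample:
    draws: list[Draw] = field(default_factory=list)
    run_id: str = "run1"

    def __post_init__(self):
        cycles = [d.cycle for d in self.draws]
        if any(b <= a for a, b in zip(cycles, cycles[1:])):
            raise ValueError("cycle numbers must be strictly increasing")
        for d in self.draws:
            if d.lnL != d.lnL or d.lnL in (float("inf"),):
                raise ValueError(f"non-finite lnL at cycle {d.cycle}")

    def __len__(self) -> int:
        return len(self.draws)

    def __iter__(self):
        return iter(self.draws)

    @property
    def trees(self) -> list[PhyloTree]:
        return [d.tree for d in self.draws]

    @property
    def lnLs(self) -> list[float]:
        return [d.lnL for d in self.draws]

    def discard_burnin(self, fraction: float) -> "TreeSample":
        """Drop the first floor(fraction * n) draws."""
        if not 0.0 <= fraction < 1.0:
            raise ValueError("burnin fraction must be in [0, 1)")
        cut = int(fraction * len(self.draws))
        return TreeSample(draws=self.draws[cut:], run_id=self.run_id)


def write_tree_sample(sample: TreeSample, prefix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.p", "w", encoding="utf-8") as p:
        p.write("cycle\tlnL\talpha\n")
        for d in sample:
            alpha = "NA" if d.alpha is None else f"{d.alpha:.12g}"
            p.write(f"{d.cycle}\t{d.lnL:.12g}\t{alpha}\n")
    with open(f"{prefix}.t", "w", encoding="utf-8") as t:
        t.write("cycle\ttree\n")
        for d in sample:
            t.write(f"{d.cycle}\t{d.tree.to_newick()}\n")


def read_tree_sample(prefix) -> TreeSample:
    prefix = Path(prefix)
    params: list[tuple[int, float, float | None]] = []
    with open(f"{prefix}.p", encoding="utf-8") as p:
        header = p.readline().strip().split("\t")
        if header[:2] != ["cycle", "lnL"]:
            raise ValueError(f"{prefix}.p: unexpected header {header}")
        for line in p:
            cycle_s, lnl_s, alpha_s = line.rstrip("\n").split("\t")
            alpha = None if alpha_s == "NA" else float(alpha_s)
            params.append((int(cycle_s), float(lnl_s), alpha))
    draws = []
    with open(f"{prefix}.t", encoding="utf-8") as t:
        t.readline()
        for i, line in enumerate(t):
            cycle_s, newick = line.rstrip("\n").split("\t", 1)
            if i >= len(params):
                raise ValueError(f"{prefix}: more trees than parameter rows")
            cycle, lnl, alpha = params[i]
            if int(cycle_s) != cycle:
                raise ValueError(
                    f"{prefix}: cycle mismatch between .t ({cycle_s}) and "
                    f".p ({cycle}) at row {i + 1}")
            draws.append(Draw(cycle=cycle, tree=PhyloTree.from_newick(newick),
                              lnL=lnl, alpha=alpha))
    if len(draws) != len(params):
        raise ValueError(f"{prefix}: fewer trees than parameter rows")
    return TreeSample(draws=draws, run_id=prefix.name)
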