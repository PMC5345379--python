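"""Character coding: median binarization of quantitative traits and
majority coding of polymorphic qualitative observations.

Quantitative characters are species means of measurement ratios (or mean
angles); each is reduced to a binary character by splitting at the
across-species median.  Qualitative characters observed more than once per
species are reduced to the modal state; exact ties are retained as
polymorphism sets.
"""

from __future__ import annotations

import statistics
import warnings
from collections import Counter
from dataclasses import dataclass, replace

import pandas as pd

from .matrix import CharacterMatrix, CharacterMeta

__all__ = [
    "binarize_quantitative", "majority_code", "code_matrix",
    "QuantitativeTable", "CodingReport",
]


@dataclass
class QuantitativeTable:
    """Per-taxon values for quantitative characters; NaN/None = missing."""

    taxa: list[str]
    values: dict[int, list[float | None]]  # 1-based character -> per-taxon

    @classmethod
    def from_tsv(cls, path) -> "QuantitativeTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = {
            int(col): [None if pd.isna(v) else float(v) for v in df[col]]
            for col in df.columns
        }
        return cls(taxa=list(df.index), values=values)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {str(c): [float("nan") if v is None else v for v in col]
             for c, col in self.values.items()},
            index=self.taxa,
        )
        df.index.name = "taxon"
        df.to_csv(path, sep="\t")


def binarize_quantitative(values, tie_state: int = 0):
    """Bin per-taxon values at the across-taxa median.

    State 1 iff the value exceeds the median of the non-missing values;
    values at or below the median get state 0 (``tie_state=1`` flips the
    boundary case).  Missing (None/NaN) stays missing (returned as None).
    The median of an even count is the midpoint of the central order
    statistics, so the boundary rule only matters for odd counts and exact
    midpoint ties.
    """
    present = [v for v in values if v is not None and v == v]
    if not present:
        raise ValueError("cannot binarize: all values missing")
    med = statistics.median(present)
    if len(set(present)) == 1:
        warnings.warn("constant quantitative character (all values equal)",
                      stacklevel=2)
    out = []
    for v in values:
        if v is None or v != v:
            out.append(None)
        elif v > med:
            out.append(1)
        elif v < med:
            out.append(0)
        else:
            out.append(tie_state)
    return out


def majority_code(observations) -> frozenset[int]:
    """Modal state of a multiset of observed states for one species;
    exact ties are kept as a polymorphism set."""
    counts = Counter(observations)
    if not counts:
        raise ValueError("majority_code requires at least one observation")
    top = max(counts.values())
    return frozenset(s for s, c in counts.items() if c == top)


@dataclass
class CodingReport:
    rows: list[dict]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.rows).to_csv(path, sep="\t", index=False)

    @property
    def constant_characters(self) -> list[int]:
        return [r["character"] for r in self.rows if r["constant"]]


def code_matrix(qual_observations: dict[tuple[str, int], list[int]] | None,
                quant_table: QuantitativeTable | None,
                meta: list[CharacterMeta],
                tie_state: int = 0):
    """Assemble the analysis matrix from raw observations.

    ``qual_observations`` maps (taxon, 1-based character) to the multiset of
    states observed within that species; ``quant_table`` carries species
    means for the quantitative characters.  Returns (CharacterMatrix,
    CodingReport).  Autapomorphies are retained as coded.
    """
    taxa = None
    if quant_table is not None:
        taxa = list(quant_table.taxa)
    if qual_observations:
        qual_taxa = sorted({t for t, _ in qual_observations},
                           key=lambda t: (taxa.index(t) if taxa and t in taxa
                                          else len(taxa or [])))
        if taxa is None:
            taxa = qual_taxa
        else:
            extra = [t for t in qual_taxa if t not in taxa]
            if extra:
                raise ValueError(
                    f"taxa present in qualitative observations only: {extra}")
    if not taxa:
        raise ValueError("no taxa to code")

    columns: dict[int, list[frozenset[int]]] = {}
    report_rows = []
    out_meta = []
    for m in meta:
        full = frozenset(range(m.k))
        if m.kind == "quantitative":
            if quant_table is None or m.index not in quant_table.values:
                raise ValueError(f"no quantitative values for character {m.index}")
            vals = quant_table.values[m.index]
            try:
                states = binarize_quantitative(vals, tie_state=tie_state)
            except ValueError as err:
                raise ValueError(f"character {m.index}: {err}") from None
            col = [frozenset({0, 1}) if s is None else frozenset({s})
                   for s in states]
            out_meta.append(replace(m, k=2))
        else:
            col = []
            for t in taxa:
                obs = (qual_observations or {}).get((t, m.index))
                col.append(full if not obs else majority_code(obs))
            out_meta.append(replace(m))
        observed = set()
        n_missing = 0
        for cell, mm in zip(col, [out_meta[-1]] * len(col)):
            if cell == frozenset(range(mm.k)):
                n_missing += 1
            else:
                observed |= cell
        report_rows.append({
            "character": m.index, "k": out_meta[-1].k,
            "constant": len(observed) <= 1, "n_missing": n_missing,
        })
        columns[m.index] = col

    cells = [[columns[m.index][i] for m in meta] for i in range(len(taxa))]
    matrix = CharacterMatrix(taxa=taxa, cells=cells, char_meta=out_meta)
    return matrix, CodingReport(rows=report_rows)
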