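"""Discrete morphological character matrix and per-character metadata.

Cells hold *state sets*: a singleton for an ordinary observation, a larger
set for a polymorphism such as ``(01)``, and the full set of states for
missing data (``?`` or the gap symbol).  Character numbering is 1-based in
every user-facing interface, matching the conventions of morphological data
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["CharacterMeta", "CharacterMatrix"]


@dataclass
class CharacterMeta:
    """Per-character bookkeeping: 1-based index, qualitative/quantitative
    kind, ordered flag, state count k, inclusion flag and free-text label."""

    index: int
    kind: str = "qualitative"  # or "quantitative"
    ordered: bool = False
    k: int = 2
    included: bool = True
    label: str = ""

    def __post_init__(self):
        if self.k < 1:
            raise ValueError(f"character {self.index}: k must be >= 1, got {self.k}")
        if self.kind not in ("qualitative", "quantitative"):
            raise ValueError(f"character {self.index}: unknown kind {self.kind!r}")


@dataclass
class CharacterMatrix:
    """Taxa x characters matrix of state sets.

    ``cells[i][j]`` is the state set of taxon ``taxa[i]`` at character
    ``j`` (0-based internally; metadata indices are 1-based).  A cell is
    never empty: missing data is the full state set {0..k-1}.
    """

    taxa: list[str]
    cells: list[list[frozenset[int]]]
    char_meta: list[CharacterMeta] = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon labels must be unique")
        widths = {len(row) for row in self.cells}
        if len(self.cells) != len(self.taxa):
            raise ValueError("one cell row per taxon required")
        if self.cells and len(widths) != 1:
            raise ValueError("ragged matrix: rows differ in length")
        if not self.char_meta:
            self.char_meta = [
                CharacterMeta(index=j + 1, k=self._observed_k(j))
                for j in range(self.n_char)
            ]
        if len(self.char_meta) != self.n_char:
            raise ValueError("char_meta length must equal number of characters")
        for j, meta in enumerate(self.char_meta):
            if meta.index != j + 1:
                raise ValueError("character indices must be contiguous from 1")
            for i, row in enumerate(self.cells):
                cell = row[j]
                if not cell:
                    raise ValueError(
                        f"empty state set at taxon {self.taxa[i]!r}, character {j + 1}"
                    )
                if any(s < 0 or s >= meta.k for s in cell):
                    raise ValueError(
                        f"state outside 0..{meta.k - 1} at taxon "
                        f"{self.taxa[i]!r}, character {j + 1}"
                    )

    # ------------------------------------------------------------ properties

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_char(self) -> int:
        return len(self.cells[0]) if self.cells else len(self.char_meta)

    @property
    def included_indices(self) -> list[int]:
        """1-based indices of included characters."""
        return [m.index for m in self.char_meta if m.included]

    @property
    def n_included(self) -> int:
        return len(self.included_indices)

    def column(self, index: int) -> list[frozenset[int]]:
        """Column by 1-based character index, in taxon order."""
        if not 1 <= index <= self.n_char:
            raise IndexError(f"no character {index}")
        return [row[index - 1] for row in self.cells]

    def _observed_k(self, j: int) -> int:
        states = set()
        for row in self.cells:
            states |= row[j]
        return max(len(states), max(states, default=0) + 1, 1)

    def observed_states(self, index: int, singleton_only: bool = False) -> set[int]:
        """States observed at a 1-based character, ignoring fully missing
        cells (cells equal to the whole state space)."""
        meta = self.char_meta[index - 1]
        full = frozenset(range(meta.k))
        out: set[int] = set()
        for cell in self.column(index):
            if cell == full:
                continue
            if singleton_only and len(cell) != 1:
                continue
            out |= cell
        return out

    # ------------------------------------------------------------ operations

    def apply_exclusions(self, excluded: set[int]) -> "CharacterMatrix":
        """Mark 1-based character indices as excluded from analysis.

        Numbering is preserved; downstream likelihood and parsimony skip
        excluded characters entirely.  Idempotent.
        """
        for idx in excluded:
            if not 1 <= idx <= self.n_char:
                raise ValueError(f"cannot exclude unknown character {idx}")
        meta = [
            replace(m, included=False) if m.index in excluded else replace(m)
            for m in self.char_meta
        ]
        return CharacterMatrix(
            taxa=list(self.taxa),
            cells=[list(row) for row in self.cells],
            char_meta=meta,
        )

    def drop_excluded(self) -> "CharacterMatrix":
        """Physically delete excluded columns (renumbers characters)."""
        keep = [m.index - 1 for m in self.char_meta if m.included]
        meta = [
            replace(self.char_meta[j], index=new + 1)
            for new, j in enumerate(keep)
        ]
        return CharacterMatrix(
            taxa=list(self.taxa),
            cells=[[row[j] for j in keep] for row in self.cells],
            char_meta=meta,
        )

    def subset_taxa(self, keep: list[str]) -> "CharacterMatrix":
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in keep if t not in index]
        if missing:
            raise ValueError(f"unknown taxa: {missing}")
        return CharacterMatrix(
            taxa=list(keep),
            cells=[list(self.cells[index[t]]) for t in keep],
            char_meta=[replace(m) for m in self.char_meta],
        )


def apply_exclusions(matrix: CharacterMatrix, excluded: set[int]) -> CharacterMatrix:
    """Functional alias for :meth:`CharacterMatrix.apply_exclusions`."""
    return matrix.apply_exclusions(excluded)
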