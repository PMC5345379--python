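"""NEXUS reading/writing for standard (morphological) data matrices.

Supports the MrBayes-compatible subset: a DATA/CHARACTERS block with
``FORMAT DATATYPE=STANDARD SYMBOLS="0123..." MISSING=? GAP=-``, polymorphism
groups ``(01)``/``{01}``, and an ASSUMPTIONS block whose ``ctype ordered:``
and ``exset`` commands populate the ordered and included flags of the
character metadata.  The gap symbol is treated as missing data.  Two
auxiliary ASSUMPTIONS-block annotations, ``charset quantitative`` and a
``[KMAX ...]`` comment, let a written file round-trip its full metadata
while remaining valid for MrBayes and PAUP*.
"""

from __future__ import annotations

import re
from pathlib import Path

from .matrix import CharacterMatrix, CharacterMeta

__all__ = ["read_nexus", "write_nexus", "NexusError"]


class NexusError(ValueError):
    """Malformed NEXUS input."""


_TOKEN = re.compile(r"'(?:[^']|'')*'|[^\s]+")


def _strip_comments(text: str, keep: list[str]) -> str:
    """Remove [...] comments, stashing KMAX annotations in ``keep``."""
    out, depth, buf = [], 0, []
    for ch in text:
        if ch == "[":
            depth += 1
            if depth == 1:
                buf = []
                continue
        if ch == "]" and depth:
            depth -= 1
            if depth == 0:
                keep.append("".join(buf))
                continue
        if depth:
            buf.append(ch)
        else:
            out.append(ch)
    if depth:
        raise NexusError("unterminated comment")
    return "".join(out)


def _unquote(tok: str) -> str:
    if tok.startswith("'") and tok.endswith("'"):
        return tok[1:-1].replace("''", "'")
    return tok


def _parse_indices(tokens: list[str], n_char: int, context: str) -> set[int]:
    """1-based index lists with PAUP-style ranges ``a-b`` and ``.`` = last."""
    out: set[int] = set()
    for tok in tokens:
        tok = tok.rstrip(";")
        if not tok:
            continue
        m = re.fullmatch(r"(\d+)(?:-(\d+|\.))?", tok)
        if not m:
            raise NexusError(f"bad character index {tok!r} in {context}")
        lo = int(m.group(1))
        hi = m.group(2)
        hi = n_char if hi == "." else (int(hi) if hi else lo)
        for i in range(lo, hi + 1):
            if not 1 <= i <= n_char:
                raise NexusError(f"character index {i} out of range in {context}")
            out.add(i)
    return out


def read_nexus(path) -> CharacterMatrix:
    text = Path(path).read_text(encoding="utf-8")
    kept_comments: list[str] = []
    text = _strip_comments(text, kept_comments)
    if not text.lstrip().upper().startswith("#NEXUS"):
        raise NexusError("not a NEXUS file (missing #NEXUS header)")
    body = text.lstrip()[6:]
    # split into ;-terminated commands, tracking blocks
    commands = [c.strip() for c in body.split(";")]
    block = None
    ntax = nchar = None
    symbols = "0123456789"
    missing, gap = "?", "-"
    matrix_cmd = None
    ordered: set[int] = set()
    excluded: set[int] = set()
    quantitative: set[int] = set()

    pending = []
    for cmd in commands:
        if not cmd:
            continue
        toks = _TOKEN.findall(cmd)
        head = toks[0].upper()
        if head == "BEGIN":
            block = toks[1].upper() if len(toks) > 1 else None
            continue
        if head in ("END", "ENDBLOCK"):
            block = None
            continue
        if block in ("DATA", "CHARACTERS"):
            if head == "DIMENSIONS":
                for t in toks[1:]:
                    m = re.fullmatch(r"(?i)NTAX\s*=\s*(\d+)", t)
                    if m:
                        ntax = int(m.group(1))
                    m = re.fullmatch(r"(?i)NCHAR\s*=\s*(\d+)", t)
                    if m:
                        nchar = int(m.group(1))
            elif head == "FORMAT":
                joined = " ".join(toks[1:])
                m = re.search(r'(?i)SYMBOLS\s*=\s*"([^"]*)"', joined)
                if m:
                    symbols = m.group(1).replace(" ", "")
                m = re.search(r"(?i)MISSING\s*=\s*(\S)", joined)
                if m:
                    missing = m.group(1)
                m = re.search(r"(?i)GAP\s*=\s*(\S)", joined)
                if m:
                    gap = m.group(1)
            elif head == "MATRIX":
                matrix_cmd = cmd[len(toks[0]):]
        elif block == "ASSUMPTIONS":
            pending.append(toks)
    if nchar is None or matrix_cmd is None:
        raise NexusError("missing DIMENSIONS NCHAR or MATRIX command")

    taxa, rows = _parse_matrix(matrix_cmd, nchar, symbols, missing, gap)
    if ntax is not None and len(taxa) != ntax:
        raise NexusError(f"NTAX={ntax} but matrix has {len(taxa)} taxa")

    for toks in pending:
        head = toks[0].upper()
        if head == "CTYPE":
            rest = " ".join(toks[1:])
            m = re.match(r"(?i)\s*(ord\w*)\s*:\s*(.*)", rest)
            if m:
                ordered |= _parse_indices(m.group(2).split(), nchar, "ctype")
        elif head == "EXSET":
            rest = " ".join(toks[1:])
            m = re.match(r".*?=\s*(.*)", rest)
            if m:
                excluded |= _parse_indices(m.group(1).split(), nchar, "exset")
        elif head == "CHARSET" and len(toks) > 1 and \
                toks[1].lower() == "quantitative":
            rest = " ".join(toks[2:])
            m = re.match(r"\s*=\s*(.*)", rest)
            if m:
                quantitative |= _parse_indices(m.group(1).split(), nchar, "charset")

    kmax = None
    for comment in kept_comments:
        m = re.match(r"\s*KMAX((?:\s+\d+)+)\s*$", comment)
        if m:
            kmax = [int(x) for x in m.group(1).split()]
    # per-character k: observed states unless declared via KMAX
    meta = []
    for j in range(nchar):
        observed = set()
        for row in rows:
            if row[j] is not None:
                observed |= row[j]
        if kmax is not None:
            k = kmax[j]
        else:
            k = max(len(observed), max(observed, default=0) + 1, 2)
        meta.append(CharacterMeta(
            index=j + 1,
            kind="quantitative" if j + 1 in quantitative else "qualitative",
            ordered=j + 1 in ordered,
            k=k,
            included=j + 1 not in excluded,
        ))
    cells = []
    for row in rows:
        cells.append([
            frozenset(range(meta[j].k)) if row[j] is None else frozenset(row[j])
            for j in range(nchar)
        ])
    return CharacterMatrix(taxa=taxa, cells=cells, char_meta=meta)


def _parse_matrix(text: str, nchar: int, symbols: str, missing: str, gap: str):
    state_of = {ch: i for i, ch in enumerate(symbols)}
    taxa: list[str] = []
    rows: list[list] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        m = _TOKEN.match(line)
        label = _unquote(m.group(0))
        seq = line[m.end():].strip()
        if label in taxa:
            # interleaved continuation
            row = rows[taxa.index(label)]
        else:
            taxa.append(label)
            rows.append([])
            row = rows[-1]
        i = 0
        while i < len(seq):
            ch = seq[i]
            if ch.isspace():
                i += 1
                continue
            if ch in (missing, gap):
                row.append(None)  # resolved to full set once k is known
                i += 1
            elif ch in "({":
                close = ")" if ch == "(" else "}"
                j = seq.find(close, i)
                if j < 0:
                    raise NexusError(f"unclosed state group for taxon {label!r}")
                group = set()
                for c in seq[i + 1:j]:
                    if c.isspace() or c == ",":
                        continue
                    if c not in state_of:
                        raise NexusError(
                            f"symbol {c!r} outside declared symbols at taxon "
                            f"{label!r}, character {len(row) + 1}")
                    group.add(state_of[c])
                if not group:
                    raise NexusError(f"empty state group for taxon {label!r}")
                row.append(group)
                i = j + 1
            elif ch in state_of:
                row.append({state_of[ch]})
                i += 1
            else:
                raise NexusError(
                    f"symbol {ch!r} outside declared symbols at taxon "
                    f"{label!r}, character {len(row) + 1}")
    for label, row in zip(taxa, rows):
        if len(row) != nchar:
            raise NexusError(
                f"taxon {label!r} has {len(row)} characters, expected {nchar}")
    return taxa, rows


def write_nexus(matrix: CharacterMatrix, path) -> None:
    kmax = max((m.k for m in matrix.char_meta), default=2)
    symbols = "0123456789"[:max(kmax, 2)]
    lines = ["#NEXUS", "", "BEGIN DATA;",
             f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_char};",
             f'FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;',
             "MATRIX"]
    width = max((len(_escape(t)) for t in matrix.taxa), default=0) + 2
    for taxon, row in zip(matrix.taxa, matrix.cells):
        cells = []
        for j, cell in enumerate(row):
            full = frozenset(range(matrix.char_meta[j].k))
            if cell == full:
                cells.append("?")
            elif len(cell) == 1:
                cells.append(str(next(iter(cell))))
            else:
                cells.append("(" + "".join(str(s) for s in sorted(cell)) + ")")
        lines.append(f"{_escape(taxon):<{width}}" + "".join(cells))
    lines += [";", "END;", "", "BEGIN ASSUMPTIONS;"]
    ordered = [m.index for m in matrix.char_meta if m.ordered]
    excluded = [m.index for m in matrix.char_meta if not m.included]
    quantitative = [m.index for m in matrix.char_meta
                    if m.kind == "quantitative"]
    if ordered:
        lines.append("ctype ordered: " + " ".join(map(str, ordered)) + ";")
    if excluded:
        lines.append("exset * excluded = " + " ".join(map(str, excluded)) + ";")
    if quantitative:
        lines.append("charset quantitative = "
                     + " ".join(map(str, quantitative)) + ";")
    lines.append("[KMAX " + " ".join(str(m.k) for m in matrix.char_meta) + "]")
    lines += ["END;", ""]
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def _escape(label: str) -> str:
    if re.search(r"[\s()\[\]{};,=']", label):
        return "'" + label.replace("'", "''") + "'"
    return label
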