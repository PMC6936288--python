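"""Discrete character–taxon matrices (NEXUS morphology-style data).

Cells are sets of integer states: a singleton for a plain score, a
multi-element set for a polymorphism (``{..}`` / ``(..)``), and the full
observed state universe of the character for missing data.  The gap symbol
``-`` is treated as missing throughout (morphological matrices conventionally
score ``-`` as inapplicable, and no computation here gives it fifth-state
semantics); which cells were gaps vs ``?`` is remembered for round-tripping.

Character indices are 1-based in every user-facing API, matching the usual
"ch. N" citation style of morphology papers; internal storage is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy

from .errors import MatrixParseError
from .tree import Tree, _from_dendropy, normalize_label

__all__ = ["CharacterMatrix", "NexusData", "parse_nexus", "write_nexus"]

_MISSING = "?"
_GAP = "-"


def _symbol_to_int(symbol: str, mapping: dict[str, int]) -> int:
    if symbol in mapping:
        return mapping[symbol]
    if symbol.isdigit():
        value = int(symbol)
    elif symbol.isalpha() and len(symbol) == 1:
        value = 10 + ord(symbol.upper()) - ord("A")
    else:
        raise MatrixParseError(f"unknown state symbol {symbol!r}")
    mapping[symbol] = value
    return value


@dataclass
class CharacterMatrix:
    """taxa x characters matrix of state sets.

    ``cells[i][j]`` is the frozenset of integer states taxon *i* may show
    for character *j* (0-based internally).  ``raw[i][j]`` keeps the symbol
    kind for writing: '?' missing, '-' gap, otherwise the scored states.
    ``ordered`` holds 1-based indices of characters scored additively.
    """

    taxa: list[str]
    cells: list[list[frozenset[int]]]
    raw: list[list[str]]
    ordered: set[int] = field(default_factory=set)
    symbol_map: dict[str, int] = field(default_factory=dict)
    true_changes: Optional[list[int]] = None  # set by the simulator

    def __post_init__(self):
        n = self.n_characters
        for i, row in enumerate(self.cells):
            if len(row) != n:
                raise MatrixParseError(
                    f"taxon {self.taxa[i]!r}: row length {len(row)} != {n}")
            for j, cell in enumerate(row):
                if not cell:
                    raise MatrixParseError(
                        f"taxon {self.taxa[i]!r}, character {j + 1}: empty state set")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def is_ordered(self, char: int) -> bool:
        """*char* is 1-based."""
        return char in self.ordered

    def cell(self, taxon: str, char: int) -> frozenset[int]:
        """State set for (taxon, 1-based character index)."""
        i = self.taxa.index(normalize_label(taxon))
        return self.cells[i][char - 1]

    def is_missing(self, taxon_index: int, char: int) -> bool:
        """True if the cell was scored '?' or '-' (1-based char)."""
        return self.raw[taxon_index][char - 1] in (_MISSING, _GAP)

    def column(self, char: int) -> list[frozenset[int]]:
        """All state sets for a 1-based character index."""
        j = char - 1
        return [row[j] for row in self.cells]

    def scored_column(self, char: int) -> list[frozenset[int]]:
        """State sets of taxa actually scored (not missing/gap) for *char*."""
        j = char - 1
        return [row[j] for i, row in enumerate(self.cells)
                if self.raw[i][j] not in (_MISSING, _GAP)]

    def universe(self, char: int) -> frozenset[int]:
        """Observed state universe of a 1-based character."""
        states: set[int] = set()
        for cell in self.scored_column(char):
            states |= cell
        return frozenset(states) if states else frozenset({0})

    def with_ordered(self, ordered: Iterable[int]) -> "CharacterMatrix":
        ordered = set(ordered)
        bad = [c for c in ordered if not 1 <= c <= self.n_characters]
        if bad:
            raise MatrixParseError(f"ordered character indices out of range: {bad}")
        return CharacterMatrix(self.taxa, self.cells, self.raw,
                               ordered, dict(self.symbol_map), self.true_changes)

    @classmethod
    def from_symbols(cls, taxa: Sequence[str], rows: Sequence[str],
                     ordered: Iterable[int] = ()) -> "CharacterMatrix":
        """Build from per-taxon symbol strings, e.g. ``"01?{01}2"``.

        Accepts ``?`` missing, ``-`` gap, ``{..}`` or ``(..)`` polymorphism.
        Mainly for tests and small examples.
        """
        mapping: dict[str, int] = {}
        parsed_rows: list[list[object]] = []
        for taxon, text in zip(taxa, rows):
            row: list[object] = []
            k = 0
            while k < len(text):
                ch = text[k]
                if ch in "{(":
                    close = "}" if ch == "{" else ")"
                    end = text.index(close, k)
                    states = frozenset(_symbol_to_int(s, mapping)
                                       for s in text[k + 1:end] if not s.isspace())
                    row.append(("poly", states))
                    k = end + 1
                elif ch in (_MISSING, _GAP):
                    row.append((ch, None))
                    k += 1
                elif ch.isspace():
                    k += 1
                else:
                    row.append(("state", frozenset({_symbol_to_int(ch, mapping)})))
                    k += 1
            parsed_rows.append(row)
        return cls._assemble([normalize_label(t) for t in taxa],
                             parsed_rows, mapping, ordered)

    @classmethod
    def _assemble(cls, taxa, parsed_rows, mapping, ordered) -> "CharacterMatrix":
        lengths = {len(r) for r in parsed_rows}
        if len(lengths) > 1:
            bad = [t for t, r in zip(taxa, parsed_rows)
                   if len(r) != len(parsed_rows[0])]
            raise MatrixParseError(f"ragged matrix rows for taxa: {bad}")
        n_char = len(parsed_rows[0]) if parsed_rows else 0
        # per-character observed universe, for expanding missing cells
        universes: list[set[int]] = [set() for _ in range(n_char)]
        for row in parsed_rows:
            for j, (kind, states) in enumerate(row):
                if states:
                    universes[j] |= states
        cells, raw = [], []
        for row in parsed_rows:
            crow, rrow = [], []
            for j, (kind, states) in enumerate(row):
                if kind in (_MISSING, _GAP):
                    crow.append(frozenset(universes[j]) or frozenset({0}))
                    rrow.append(kind)
                else:
                    crow.append(states)
                    rrow.append("".join(sorted(
                        next(s for s, v in mapping.items() if v == st)
                        for st in states)) if len(states) > 1 else
                        next(s for s, v in mapping.items() if v == next(iter(states))))
            cells.append(crow)
            raw.append(rrow)
        return cls(list(taxa), cells, raw, set(ordered), mapping)


@dataclass
class NexusData:
    """Parsed NEXUS content: a character matrix and/or named trees."""

    matrix: Optional[CharacterMatrix] = None
    trees: dict[str, Tree] = field(default_factory=dict)


def parse_nexus(text: str, ordered: Iterable[int] = ()) -> NexusData:
    """Parse NEXUS DATA/CHARACTERS and/or TREES blocks.

    Interleaved and flat MATRIX layouts are accepted; TRANSLATE tables are
    resolved.  ``?`` expands to the observed state universe of its
    character, ``{..}``/``(..)`` to the listed set, and ``-`` (gap) is
    recorded and treated as missing.  *ordered* supplies 1-based indices of
    additively scored characters (sidecar convention; ASSUMPTIONS blocks are
    not interpreted).
    """
    ds = dendropy.DataSet()
    try:
        ds.read(data=text, schema="nexus", preserve_underscores=True)
    except Exception as exc:
        raise MatrixParseError(f"could not parse NEXUS: {exc}") from exc

    out = NexusData()
    matrices = [m for m in ds.char_matrices]
    if matrices:
        if len(matrices) > 1:
            raise MatrixParseError("multiple character matrices in one file")
        out.matrix = _matrix_from_dendropy(matrices[0]).with_ordered(ordered)
    for tree_list in ds.tree_lists:
        for k, dtree in enumerate(tree_list):
            name = dtree.label or f"tree_{k + 1}"
            out.trees[name] = _from_dendropy(dtree)
    if out.matrix is None and not out.trees:
        raise MatrixParseError("NEXUS file contains no DATA/CHARACTERS or TREES block")
    return out


def _matrix_from_dendropy(dm) -> CharacterMatrix:
    mapping: dict[str, int] = {}
    taxa, parsed_rows = [], []
    for taxon in dm:
        taxa.append(normalize_label(taxon.label))
        row: list[object] = []
        for j, state in enumerate(dm[taxon]):
            symbol = state.symbol
            fundamentals = [s for s in (state.fundamental_symbols or ())
                            if s not in (_MISSING, _GAP)]
            if symbol == _MISSING:
                row.append((_MISSING, None))
            elif symbol == _GAP:
                row.append((_GAP, None))
            elif symbol is not None and symbol not in (_MISSING, _GAP):
                try:
                    row.append(("state",
                                frozenset({_symbol_to_int(symbol, mapping)})))
                except MatrixParseError as exc:
                    raise MatrixParseError(
                        f"taxon {taxon.label!r}, character {j + 1}: {exc}") from exc
            else:
                # polymorphic/ambiguous multi-state cell
                states = frozenset(_symbol_to_int(s, mapping) for s in fundamentals)
                if not states:
                    row.append((_MISSING, None))
                else:
                    row.append(("poly", states))
        parsed_rows.append(row)
    if not parsed_rows:
        raise MatrixParseError("character matrix has no rows")
    return CharacterMatrix._assemble(taxa, parsed_rows, mapping, set())


def _cell_symbol(matrix: CharacterMatrix, i: int, j: int) -> str:
    raw = matrix.raw[i][j]
    if raw in (_MISSING, _GAP):
        return raw
    states = sorted(matrix.cells[i][j])
    inv = {v: s for s, v in matrix.symbol_map.items()}
    symbols = "".join(inv.get(s, str(s)) for s in states)
    return symbols if len(states) == 1 else "{" + symbols + "}"


def write_nexus(matrix: CharacterMatrix) -> str:
    """Serialize a CharacterMatrix to a flat NEXUS DATA block; round-trips
    through :func:`parse_nexus` preserving every cell's state set."""
    all_states = sorted({s for row in matrix.cells for cell in row for s in cell})
    inv = {v: s for s, v in matrix.symbol_map.items()}
    symbols = "".join(inv.get(s, str(s)) for s in all_states)
    width = max(len(t) for t in matrix.taxa) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        f'FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;',
        "MATRIX",
    ]
    for i, taxon in enumerate(matrix.taxa):
        body = "".join(_cell_symbol(matrix, i, j)
                       for j in range(matrix.n_characters))
        lines.append(f"{taxon:<{width}}{body}")
    lines += [";", "END;", ""]
    return "\n".join(lines)
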