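"""Categorical data tables with per-value row-set bitmask indexes.

The input dialect is a header-first CSV, comma or semicolon separated, whose
cells are single printable ASCII characters. An empty cell is N/A; a longer
cell is truncated to its first character after stripping surrounding
whitespace. Different characters are different values ('Y' != 'y').

Parsing builds, for every (column, value) pair, the exact set of rows holding
that value, stored as a bitmask so that boolean rule evaluation runs
word-parallel over 64-row blocks (a Python int is an array of machine words;
``&``, ``|`` and ``bit_count`` operate on whole words at once).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import ContractError, FormatError

#: N/A is represented in-memory as None; on disk it is the empty cell.
NA = None


@dataclass(frozen=True)
class RowSet:
    """An immutable set of row indices packed into a bitmask of width ``n``.

    Bit i is set iff row i (0-based, file order) belongs to the set. All bits
    at positions >= n are zero by construction.
    """

    mask: int
    n: int

    @property
    def cardinality(self) -> int:
        return self.mask.bit_count()

    def __and__(self, other: "RowSet") -> "RowSet":
        self._check_width(other)
        return RowSet(self.mask & other.mask, self.n)

    def __or__(self, other: "RowSet") -> "RowSet":
        self._check_width(other)
        return RowSet(self.mask | other.mask, self.n)

    def __contains__(self, row: int) -> bool:
        return 0 <= row < self.n and bool(self.mask >> row & 1)

    def indices(self) -> list[int]:
        """Row indices in ascending order (for reports and tests)."""
        return [i for i in range(self.n) if self.mask >> i & 1]

    def _check_width(self, other: "RowSet") -> None:
        if self.n != other.n:
            raise ContractError(
                f"row-set width mismatch: {self.n} vs {other.n}"
            )

    @classmethod
    def empty(cls, n: int) -> "RowSet":
        return cls(0, n)

    @classmethod
    def universe(cls, n: int) -> "RowSet":
        return cls((1 << n) - 1, n)

    @classmethod
    def from_indices(cls, rows: Iterable[int], n: int) -> "RowSet":
        mask = 0
        for r in rows:
            if not 0 <= r < n:
                raise ContractError(f"row index {r} outside [0, {n})")
            mask |= 1 << r
        return cls(mask, n)


@dataclass(frozen=True)
class ColumnSpec:
    """One table column: its name, position, observed value domain and N/A count.

    The domain never contains the N/A marker; a column whose cells are all N/A
    has an empty domain and is kept in the table but is unusable in rules.
    """

    name: str
    index: int
    domain: frozenset[str]
    na_count: int


class DataTable:
    """An indexed categorical table.

    ``index`` maps (column index, value character) to the RowSet of rows
    holding that value. For each column the row sets of its distinct values
    are pairwise disjoint and, together with the column's N/A rows, partition
    the full row range.
    """

    def __init__(
        self,
        columns: list[ColumnSpec],
        n_rows: int,
        index: Mapping[tuple[int, str], RowSet],
        delimiter: str = ",",
    ) -> None:
        self.columns = list(columns)
        self.n_rows = n_rows
        self.index = dict(index)
        self.delimiter = delimiter
        self._by_name = {c.name: c for c in self.columns}

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def column(self, ref: int | str) -> ColumnSpec:
        if isinstance(ref, str):
            try:
                return self._by_name[ref]
            except KeyError:
                raise FormatError(f"no column named {ref!r}") from None
        try:
            return self.columns[ref]
        except IndexError:
            raise FormatError(f"no column with index {ref}") from None

    def rowset(self, column: int, value: str) -> RowSet:
        """Rows where ``column`` holds ``value``; empty if the value never occurs."""
        return self.index.get((column, value), RowSet.empty(self.n_rows))

    def usable_columns(self) -> list[int]:
        """Indices of columns with a non-empty domain (eligible for rules)."""
        return [c.index for c in self.columns if c.domain]

    def cell(self, row: int, column: int) -> str | None:
        """Reconstruct one cell from the index (None = N/A)."""
        for value in self.columns[column].domain:
            if row in self.index[(column, value)]:
                return value
        return NA

    def to_csv(self, delimiter: str | None = None) -> str:
        """Serialize back to the input dialect (N/A as empty cell)."""
        d = delimiter or self.delimiter
        lines = [d.join(c.name for c in self.columns)]
        for r in range(self.n_rows):
            lines.append(d.join(self.cell(r, c.index) or "" for c in self.columns))
        return "\n".join(lines) + "\n"


def detect_delimiter(first_line: str) -> str:
    """Choose ';' or ',' by majority count in the header line.

    The dialect allows either separator but never marks which one is in use;
    the header (a list of names, which cannot themselves contain the
    separator) votes. Ties and separator-free headers fall back to ','.
    """
    if not first_line:
        raise FormatError("empty header line")
    return ";" if first_line.count(";") > first_line.count(",") else ","


def normalize_cell(raw: str) -> str | None:
    """Apply the single-character cell convention.

    Surrounding whitespace is stripped; an empty result is N/A; otherwise the
    first character is the value. Raises ValueError (wrapped into a located
    FormatError by :func:`parse_table`) for non-printable-ASCII characters.
    """
    stripped = raw.strip()
    if not stripped:
        return NA
    ch = stripped[0]
    if not 33 <= ord(ch) <= 126:
        raise ValueError(f"character {ch!r} is outside printable ASCII")
    return ch


def parse_table(source: str | Iterable[str]) -> DataTable:
    """Parse CSV text (or an iterable of lines) into a :class:`DataTable`.

    Raises FormatError on an empty stream, duplicate header names, ragged
    rows (named by line number) or non-ASCII cell values (named by row and
    column). No quoting is honored: single-character cells cannot contain
    the delimiter.
    """
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = [ln.rstrip("\r\n") for ln in source]
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        raise FormatError("empty input: expected a header line and data rows")

    delimiter = detect_delimiter(lines[0])
    names = [name.strip() for name in lines[0].split(delimiter)]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise FormatError(f"duplicate header names: {', '.join(dupes)}")
    n_cols = len(names)

    if len(lines) < 2:
        raise FormatError("no data rows after the header")

    masks: dict[tuple[int, str], int] = {}
    na_counts = [0] * n_cols
    n_rows = 0
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split(delimiter)
        if len(cells) != n_cols:
            raise FormatError(
                f"line {lineno}: expected {n_cols} fields, found {len(cells)}"
            )
        row = n_rows
        for ci, raw in enumerate(cells):
            try:
                value = normalize_cell(raw)
            except ValueError as exc:
                raise FormatError(
                    f"line {lineno}, column {names[ci]!r}: {exc}"
                ) from None
            if value is NA:
                na_counts[ci] += 1
            else:
                masks[(ci, value)] = masks.get((ci, value), 0) | (1 << row)
        n_rows += 1

    columns = [
        ColumnSpec(
            name=names[ci],
            index=ci,
            domain=frozenset(v for (c, v) in masks if c == ci),
            na_count=na_counts[ci],
        )
        for ci in range(n_cols)
    ]
    index = {key: RowSet(mask, n_rows) for key, mask in masks.items()}
    return DataTable(columns, n_rows, index, delimiter)


def read_table(path: str) -> DataTable:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_table(fh)
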