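"""Rule patterns and rule expressions.

A rule pattern is a template like ``_ AND (_ OR _) -> _``: a left-hand side
that is a conjunction of clauses, each clause a disjunction of slots, implying
a right-hand side of exactly one slot. Slots are either blanks (to be filled
by the miner) or elementary equalities such as ``age=AB``, which states that
the ``age`` column holds one of the characters 'A' or 'B'.

Everything is normalized to AND-of-OR-clauses form at parse time: ANDs nested
in parentheses are flattened into top-level clauses, ORs nested in ORs are
flattened into one clause, and an OR applied to a conjunction is rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import TYPE_CHECKING, Union

from .errors import ContractError, PatternError

if TYPE_CHECKING:  # pragma: no cover
    from .table import DataTable


@dataclass(frozen=True)
class Blank:
    """An unfilled slot in a rule pattern."""

    def __repr__(self) -> str:
        return "Blank()"


BLANK = Blank()


@dataclass(frozen=True, order=True)
class Equality:
    """An elementary equality: column ``column`` holds one of ``values``.

    ``values`` is a non-empty sorted tuple of single characters. N/A cells
    never satisfy an equality. The dataclass ordering (column, then value
    tuple) is the canonical slot order used throughout the miner.
    """

    column: int
    values: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.values:
            raise ContractError("an equality needs at least one value")
        if tuple(sorted(self.values)) != self.values:
            object.__setattr__(self, "values", tuple(sorted(self.values)))

    def render(self, table: "DataTable") -> str:
        return f"{table.columns[self.column].name}={''.join(self.values)}"


Slot = Union[Blank, Equality]
Clause = tuple[Slot, ...]


@dataclass(frozen=True)
class RulePattern:
    """An AND-of-OR-clauses LHS plus a single-slot RHS."""

    lhs_clauses: tuple[Clause, ...]
    rhs: Slot

    @property
    def n_blanks(self) -> int:
        slots = [s for cl in self.lhs_clauses for s in cl] + [self.rhs]
        return sum(isinstance(s, Blank) for s in slots)

    @property
    def is_all_blank(self) -> bool:
        return self.n_blanks == 1 + sum(len(cl) for cl in self.lhs_clauses)

    def clause_sizes(self) -> tuple[int, ...]:
        return tuple(len(cl) for cl in self.lhs_clauses)


_EQ_RE = re.compile(r"^([^\s()=]+)=([^\s()=]+)$")


def _tokenize(text: str) -> list[str]:
    padded = (
        text.replace("→", " -> ")
        .replace("->", " -> ")
        .replace("(", " ( ")
        .replace(")", " ) ")
    )
    # the first replace may produce " -> " twice for "→"; collapse is harmless
    tokens = padded.split()
    out = []
    for tok in tokens:
        if tok in {"(", ")", "->"}:
            out.append(tok)
        elif tok.upper() in {"AND", "OR"}:
            out.append(tok.upper())
        elif tok in {"_", "□"}:
            out.append("_")
        elif _EQ_RE.match(tok):
            out.append(tok)
        else:
            raise PatternError(f"unknown token {tok!r}")
    return out


def _parse_atom_token(tok: str, table: "DataTable | None") -> Slot:
    if tok == "_":
        return BLANK
    m = _EQ_RE.match(tok)
    assert m is not None
    if table is None:
        raise PatternError(
            f"equality {tok!r} requires a table context to resolve the column name"
        )
    col = table.column(m.group(1))
    return Equality(col.index, tuple(sorted(set(m.group(2)))))


def _parse_expr(
    tokens: list[str], pos: int, depth: int, table: "DataTable | None"
) -> tuple[list[list[Slot]], int]:
    """Parse a (sub)expression into normalized clause lists.

    Returns AND-of-OR clauses. OR is only legal inside parentheses and only
    between disjunction-free operands (no ORs of ANDs).
    """

    def parse_item(pos: int) -> tuple[list[list[Slot]], int]:
        if pos >= len(tokens):
            raise PatternError("unexpected end of expression")
        tok = tokens[pos]
        if tok == "(":
            inner, pos = _parse_expr(tokens, pos + 1, depth + 1, table)
            if pos >= len(tokens) or tokens[pos] != ")":
                raise PatternError("unbalanced parentheses")
            return inner, pos + 1
        if tok in {")", "AND", "OR", "->"}:
            raise PatternError(f"unexpected token {tok!r}")
        return [[_parse_atom_token(tok, table)]], pos + 1

    items: list[list[list[Slot]]] = []
    ops: list[str] = []
    item, pos = parse_item(pos)
    items.append(item)
    while pos < len(tokens) and tokens[pos] in {"AND", "OR"}:
        ops.append(tokens[pos])
        item, pos = parse_item(pos + 1)
        items.append(item)

    if not ops:
        return items[0], pos
    if len(set(ops)) > 1:
        raise PatternError(
            "mixing AND and OR at one level is ambiguous; parenthesize"
        )
    if ops[0] == "AND":
        clauses: list[list[Slot]] = []
        for it in items:
            clauses.extend(it)  # flatten nested ANDs
        return clauses, pos
    # OR
    if depth == 0:
        raise PatternError("OR is only allowed inside parentheses")
    merged: list[Slot] = []
    for it in items:
        if len(it) != 1:
            raise PatternError("OR cannot be applied to a conjunction")
        merged.extend(it[0])  # flatten nested ORs
    return [merged], pos


def parse_pattern(text: str, table: "DataTable | None" = None) -> RulePattern:
    """Parse a pattern (or a fully filled rule expression) into normal form.

    Accepts '□' and '_' for blanks, '→' and '->' for implication. When
    ``table`` is given, ``name=values`` equalities are accepted as slots, so
    rendered rules round-trip through this parser.
    """
    if not text.strip():
        raise PatternError("empty pattern")
    tokens = _tokenize(text)
    if tokens.count("->") != 1:
        raise PatternError("a rule needs exactly one implies sign")
    arrow = tokens.index("->")
    lhs_tokens, rhs_tokens = tokens[:arrow], tokens[arrow + 1 :]
    if not lhs_tokens:
        raise PatternError("missing left-hand side")
    if not rhs_tokens:
        raise PatternError("missing right-hand side")

    lhs_clauses, pos = _parse_expr(lhs_tokens, 0, 0, table)
    if pos != len(lhs_tokens):
        raise PatternError("unbalanced parentheses")
    rhs_clauses, pos = _parse_expr(rhs_tokens, 0, 0, table)
    if pos != len(rhs_tokens):
        raise PatternError("unbalanced parentheses")
    if len(rhs_clauses) != 1 or len(rhs_clauses[0]) != 1:
        raise PatternError(
            "the right-hand side of a rule must consist of a single blank"
        )
    for cl in lhs_clauses:
        if not cl:
            raise PatternError("empty clause")
    return RulePattern(
        tuple(tuple(cl) for cl in lhs_clauses), rhs_clauses[0][0]
    )


def render_clause(clause: Clause, table: "DataTable") -> str:
    parts = []
    for slot in clause:
        parts.append("_" if isinstance(slot, Blank) else slot.render(table))
    body = " OR ".join(parts)
    return f"({body})" if len(parts) > 1 else body


def render_expression(clauses: tuple[Clause, ...], table: "DataTable") -> str:
    return " AND ".join(render_clause(cl, table) for cl in clauses)


def render_rule(pattern: RulePattern, table: "DataTable") -> str:
    """Deterministic text form of a fully filled rule.

    Clauses joined by " AND ", multi-slot clauses parenthesized, equality
    values sorted ascending by character code. Unfilled slots are a contract
    violation (use :func:`render_pattern` for templates).
    """
    for cl in pattern.lhs_clauses:
        for slot in cl:
            if isinstance(slot, Blank):
                raise ContractError("cannot render a rule with unfilled slots")
    if isinstance(pattern.rhs, Blank):
        raise ContractError("cannot render a rule with unfilled slots")
    lhs = render_expression(pattern.lhs_clauses, table)
    return f"{lhs} -> {pattern.rhs.render(table)}"


def render_pattern(pattern: RulePattern, table: "DataTable | None" = None) -> str:
    """Text form of a (possibly partially blank) pattern."""

    def slot_text(slot: Slot) -> str:
        if isinstance(slot, Blank):
            return "_"
        if table is None:
            raise ContractError("rendering equalities requires a table")
        return slot.render(table)

    parts = []
    for cl in pattern.lhs_clauses:
        body = " OR ".join(slot_text(s) for s in cl)
        parts.append(f"({body})" if len(cl) > 1 else body)
    return f"{' AND '.join(parts)} -> {slot_text(pattern.rhs)}"


def dnf_expansion_count(clauses: tuple[Clause, ...]) -> int:
    """How many purely conjunctive LHSs an AND-of-ORs LHS compresses.

    Distributing AND over OR turns k clauses of sizes s1..sk into the OR of
    s1*...*sk conjunctions; e.g. three two-way disjunctions expand to eight
    ternary conjunctions. All LHS slots must be filled.
    """
    count = 1
    for cl in clauses:
        for slot in cl:
            if isinstance(slot, Blank):
                raise ContractError("expansion count requires a filled LHS")
        count *= len(cl)
    return count
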