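"""Rule evaluation and quality metrics.

Evaluation is word-parallel: each (column, value) pair owns a bitmask over
rows, a clause is the bitwise OR of its equalities' masks and the LHS is the
bitwise AND across clauses, so 64 rows are processed per machine word.

Metrics follow the standard frequency definitions over a table of N rows:

* support        — rows where LHS and RHS both hold
* LHS/RHS support — rows where each side holds alone
* confidence     — support / LHS support
* lift           — (support * N) / (LHS support * RHS support); 1 under
                   independence, > 1 when the LHS raises the RHS frequency
* leverage       — support/N - (LHS support/N)(RHS support/N), the additive
                   independence gap (Piatetsky-Shapiro), 0 under independence

N is the full row count; rows with N/A in a referenced column simply never
satisfy the equality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .errors import ContractError
from .pattern import Blank, Clause, Equality
from .table import DataTable, RowSet


@dataclass(frozen=True)
class RuleMetrics:
    """The six quality figures attached to every candidate rule."""

    support: int
    lhs_support: int
    rhs_support: int
    confidence: float
    lift: float
    leverage: float


def equality_rowset(table: DataTable, eq: Equality) -> RowSet:
    """Rows satisfying an elementary equality (union of per-value row sets).

    N/A rows never match. Every value must belong to the column's observed
    domain; asking for a value the column never holds is a contract error
    (the miner only enumerates domain subsets).
    """
    try:
        domain = table.columns[eq.column].domain
    except IndexError:
        raise ContractError(f"no column with index {eq.column}") from None
    if not domain:
        # column entirely N/A: nothing can match, whatever the values are
        return RowSet.empty(table.n_rows)
    result = RowSet.empty(table.n_rows)
    for v in eq.values:
        if v not in domain:
            raise ContractError(
                f"value {v!r} is not in the domain of column "
                f"{table.columns[eq.column].name!r}"
            )
        result = result | table.rowset(eq.column, v)
    return result


def evaluate_expression(table: DataTable, clauses: Iterable[Clause]) -> RowSet:
    """Rows satisfying an AND-of-ORs expression, computed on packed words.

    The empty conjunction (zero clauses) is the identity of AND and evaluates
    to all rows; this case arises transiently during simplification.
    """
    acc = RowSet.universe(table.n_rows)
    for clause in clauses:
        clause_rows = RowSet.empty(table.n_rows)
        for slot in clause:
            if isinstance(slot, Blank):
                raise ContractError("cannot evaluate an expression with blanks")
            clause_rows = clause_rows | equality_rowset(table, slot)
        acc = acc & clause_rows
    return acc


def compute_metrics(
    lhs_rows: RowSet, rhs_rows: RowSet, n_rows: int
) -> RuleMetrics | None:
    """Metrics from the two side row sets, or None when they carry no evidence.

    A rule whose LHS or RHS holds nowhere has undefined confidence/lift and is
    discarded upstream; returning None encodes that.
    """
    if n_rows <= 0:
        raise ContractError("n_rows must be positive")
    if lhs_rows.n != n_rows or rhs_rows.n != n_rows:
        raise ContractError("row-set width does not match the table")
    lhs_support = lhs_rows.cardinality
    rhs_support = rhs_rows.cardinality
    if lhs_support == 0 or rhs_support == 0:
        return None
    support = (lhs_rows & rhs_rows).cardinality
    confidence = support / lhs_support
    lift = (support * n_rows) / (lhs_support * rhs_support)
    leverage = support / n_rows - (lhs_support / n_rows) * (rhs_support / n_rows)
    # algebraic identity: lift == confidence * N / RHS support
    assert math.isclose(
        lift, confidence * n_rows / rhs_support, rel_tol=1e-12, abs_tol=1e-15
    )
    return RuleMetrics(support, lhs_support, rhs_support, confidence, lift, leverage)
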