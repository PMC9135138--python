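"""Candidate enumeration, branch-and-bound pruning, filtering and simplification.

The search fills every blank of a rule pattern with elementary equalities.
The right-hand side blank partitions the work: each permitted RHS equality is
an independent job whose results are merged, de-duplicated and sorted, so the
output is identical for any job count.

Pruning: while filling LHS clauses left to right, the support of any
completion is bounded above by |(AND of fully filled clauses) AND RHS|,
because adding further clauses can only shrink the row set. A branch whose
bound falls below the support threshold is abandoned.

Canonical enumeration kills the commutativity blow-up: inside a clause, slots
are filled in strictly increasing (column, value-set) order with distinct
columns; across clauses of equal width, fillings are forced into
non-decreasing order. Each distinct rule is therefore produced exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Sequence

from .engine import RuleMetrics, compute_metrics, equality_rowset
from .errors import ConfigError
from .pattern import Equality, RulePattern, render_rule
from .table import DataTable, RowSet

log = logging.getLogger("garm.miner")


@dataclass(frozen=True)
class SearchConfig:
    """Thresholds and structural constraints for one mining run.

    All four thresholds are inclusive (a rule passes at exactly the minimum).
    ``lhs_columns`` / ``rhs_columns`` are sets of column indices; None means
    every column with a non-empty domain. ``max_value_set_size`` caps the
    size of enumerated value sets (the full domain of a multi-valued column
    is never enumerated — it is a tautology). ``simplify_tolerance`` is the
    relative lift loss allowed while deleting LHS clauses, anchored to the
    original rule's lift.
    """

    min_support: int = 1
    min_confidence: float = 0.0
    min_lift: float = 0.0
    min_leverage: float = -0.25
    max_value_set_size: int = 2
    lhs_columns: frozenset[int] | None = None
    rhs_columns: frozenset[int] | None = None
    rhs_singleton_only: bool = True
    simplify_tolerance: float = 0.02
    max_rules: int | None = None
    jobs: int = 1

    def validate(self) -> None:
        if self.min_support < 1:
            raise ConfigError("min_support must be at least 1")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ConfigError("min_confidence must lie in [0, 1]")
        if not 0.0 <= self.simplify_tolerance < 1.0:
            raise ConfigError("simplify_tolerance must lie in [0, 1)")
        if self.max_value_set_size < 1:
            raise ConfigError("max_value_set_size must be at least 1")
        if self.jobs < 1:
            raise ConfigError("jobs must be at least 1")
        if self.max_rules is not None and self.max_rules < 1:
            raise ConfigError("max_rules must be at least 1 (or None)")
        for name in ("lhs_columns", "rhs_columns"):
            cols = getattr(self, name)
            if cols is not None and not cols:
                raise ConfigError(f"{name} must not be empty")


@dataclass(frozen=True)
class Rule:
    """A fully filled rule that passed every threshold.

    ``text`` is the canonical rendering (the de-duplication key).
    ``original_lift`` is the lift before simplification; ``simplified_from``
    holds the pre-simplification rendering when simplification changed the
    rule, else None.
    """

    clauses: tuple[tuple[Equality, ...], ...]
    rhs: Equality
    metrics: RuleMetrics
    text: str
    original_lift: float
    simplified_from: str | None = None

    def sort_key(self) -> tuple:
        return (-self.metrics.lift, -self.metrics.support, self.text)


def enumerate_equalities(
    table: DataTable, column: int, max_value_set_size: int
) -> list[Equality]:
    """All candidate value sets for one column, in canonical order.

    Non-empty subsets of the observed domain up to the size cap, ordered by
    size then by character codes. The full domain of a column with >= 2
    values is excluded: such an equality holds on every non-N/A row and adds
    no information.
    """
    domain = sorted(table.columns[column].domain)
    out: list[Equality] = []
    for size in range(1, min(max_value_set_size, len(domain)) + 1):
        if size == len(domain) >= 2:
            continue
        for subset in combinations(domain, size):
            out.append(Equality(column, subset))
    return out


def support_upper_bound(
    table: DataTable,
    partial: Sequence[Sequence[Equality | None]],
    rhs_rows: RowSet,
) -> int:
    """Sound overestimate of the support of any completion of a partial fill.

    Clauses containing an unfilled slot (None) contribute the universal set;
    fully filled clauses contribute their exact row sets. Intersecting with
    the RHS rows yields a bound that can only shrink as more clauses are
    filled, and is tight at a full leaf.
    """
    acc = rhs_rows
    for clause in partial:
        if any(slot is None for slot in clause):
            continue
        clause_rows = RowSet.empty(table.n_rows)
        for slot in clause:
            assert slot is not None
            clause_rows = clause_rows | equality_rowset(table, slot)
        acc = acc & clause_rows
    return acc.cardinality


def _canonical(clauses) -> tuple[tuple[Equality, ...], ...]:
    """Canonical clause order: AND is commutative, so rules that differ only
    by clause order must render identically (the de-duplication key)."""
    return tuple(sorted(tuple(cl) for cl in clauses))


def _passes(m: RuleMetrics, config: SearchConfig) -> bool:
    return (
        m.support >= config.min_support
        and m.confidence >= config.min_confidence
        and m.lift >= config.min_lift
        and m.leverage >= config.min_leverage
    )


@dataclass
class _Candidate:
    """One enumerated (column, value-set) pair with its cached row mask."""

    idx: int
    eq: Equality
    mask: int


@dataclass
class _SearchSpace:
    """Per-table precomputation shared by all RHS jobs."""

    candidates: list[_Candidate]
    # combos[size] = list of (idx_tuple, column_set, or_mask)
    combos: dict[int, list[tuple[tuple[int, ...], frozenset[int], int]]]
    pruned_branches: int = 0


def _build_space(
    table: DataTable, lhs_columns: Sequence[int], sizes: Sequence[int],
    max_value_set_size: int,
) -> _SearchSpace:
    candidates: list[_Candidate] = []
    for col in sorted(lhs_columns):
        for eq in enumerate_equalities(table, col, max_value_set_size):
            mask = equality_rowset(table, eq).mask
            candidates.append(_Candidate(len(candidates), eq, mask))
    combos: dict[int, list[tuple[tuple[int, ...], frozenset[int], int]]] = {}
    for size in sorted(set(sizes)):
        entries = []
        for combo in combinations(range(len(candidates)), size):
            cols = [candidates[i].eq.column for i in combo]
            if len(set(cols)) != size:
                continue  # one column may not fill two slots of one clause
            or_mask = 0
            for i in combo:
                or_mask |= candidates[i].mask
            entries.append((combo, frozenset(cols), or_mask))
        combos[size] = entries
    return _SearchSpace(candidates, combos)


def _resolve_columns(
    table: DataTable, requested: frozenset[int] | None, side: str
) -> list[int]:
    usable = set(table.usable_columns())
    if requested is None:
        cols = sorted(usable)
    else:
        bad = [c for c in requested if not 0 <= c < table.n_columns]
        if bad:
            raise ConfigError(f"{side} column indices out of range: {sorted(bad)}")
        cols = sorted(c for c in requested if c in usable)
    if not cols:
        raise ConfigError(f"no usable {side} columns")
    return cols


def rhs_candidates(table: DataTable, config: SearchConfig) -> list[Equality]:
    """The permitted RHS equalities — one mining job each."""
    cols = _resolve_columns(table, config.rhs_columns, "RHS")
    max_size = 1 if config.rhs_singleton_only else config.max_value_set_size
    out: list[Equality] = []
    for col in cols:
        out.extend(enumerate_equalities(table, col, max_size))
    return out


def fill_pattern(
    table: DataTable,
    pattern: RulePattern,
    rhs_assignment: Equality,
    config: SearchConfig,
    _space: _SearchSpace | None = None,
) -> Iterator[Rule]:
    """Depth-first fill of the LHS blanks for one fixed RHS equality.

    Yields every threshold-passing rule exactly once, in canonical order,
    backtracking whenever the support upper bound drops below ``min_support``.
    The RHS column never appears on the LHS.
    """
    sizes = pattern.clause_sizes()
    if _space is None:
        lhs_cols = [
            c
            for c in _resolve_columns(table, config.lhs_columns, "LHS")
            if c != rhs_assignment.column
        ]
        if not lhs_cols:
            return
        _space = _build_space(table, lhs_cols, sizes, config.max_value_set_size)
    space = _space
    rhs_rows = equality_rowset(table, rhs_assignment)
    if rhs_rows.cardinality < config.min_support:
        return
    n = table.n_rows
    universe = (1 << n) - 1
    rhs_col = rhs_assignment.column
    n_clauses = len(sizes)

    def rec(
        ci: int,
        lhs_mask: int,
        bound_mask: int,
        seq: tuple[tuple[int, ...], ...],
        last_by_size: dict[int, tuple[int, ...]],
    ) -> Iterator[Rule]:
        if ci == n_clauses:
            lhs_rows = RowSet(lhs_mask, n)
            metrics = compute_metrics(lhs_rows, rhs_rows, n)
            if metrics is None or not _passes(metrics, config):
                return
            clauses = _canonical(
                tuple(space.candidates[i].eq for i in combo) for combo in seq
            )
            filled = RulePattern(clauses, rhs_assignment)
            yield Rule(
                clauses=clauses,
                rhs=rhs_assignment,
                metrics=metrics,
                text=render_rule(filled, table),
                original_lift=metrics.lift,
            )
            return
        size = sizes[ci]
        floor = last_by_size.get(size)
        for combo, cols, or_mask in space.combos[size]:
            if floor is not None and combo < floor:
                continue  # symmetry: equal-width clauses in non-decreasing order
            if rhs_col in cols:
                continue
            new_lhs = lhs_mask & or_mask
            new_bound = bound_mask & or_mask
            if new_bound.bit_count() < config.min_support:
                space.pruned_branches += 1
                continue
            yield from rec(
                ci + 1, new_lhs, new_bound, seq + (combo,),
                {**last_by_size, size: combo},
            )

    yield from rec(0, universe, rhs_rows.mask, (), {})


def simplify(rule: Rule, table: DataTable, config: SearchConfig) -> Rule:
    """Greedy LHS reduction under the lift-tolerance rule.

    Candidate deletions are (a) a whole conjunct clause, when more than one
    remains, and (b) one equality out of a multi-slot clause. At each step
    the deletion with the highest resulting lift is applied (ties broken
    toward the textually smaller rule), but only while the resulting lift is
    at least (1 - tolerance) times the ORIGINAL rule's lift and the reduced
    rule still passes every threshold; otherwise the step is rolled back and
    simplification stops.
    """
    original_lift = rule.metrics.lift
    floor = (1.0 - config.simplify_tolerance) * original_lift
    rhs_rows = equality_rowset(table, rule.rhs)
    n = table.n_rows
    current = [list(cl) for cl in rule.clauses]
    current_metrics = rule.metrics

    def metrics_of(clauses: list[list[Equality]]) -> RuleMetrics | None:
        mask = (1 << n) - 1
        for cl in clauses:
            or_mask = 0
            for eq in cl:
                or_mask |= equality_rowset(table, eq).mask
            mask &= or_mask
        return compute_metrics(RowSet(mask, n), rhs_rows, n)

    changed = False
    while True:
        best: tuple[float, str, list[list[Equality]], RuleMetrics] | None = None
        for i in range(len(current)):
            options: list[list[list[Equality]]] = []
            if len(current) > 1:
                options.append([cl[:] for k, cl in enumerate(current) if k != i])
            if len(current[i]) > 1:
                for j in range(len(current[i])):
                    cand = [cl[:] for cl in current]
                    cand[i] = cand[i][:j] + cand[i][j + 1 :]
                    options.append(cand)
            for cand in options:
                m = metrics_of(cand)
                if m is None or m.lift < floor or not _passes(m, config):
                    continue  # this deletion does not qualify
                txt = render_rule(
                    RulePattern(_canonical(cand), rule.rhs), table
                )
                if best is None or m.lift > best[0] or (
                    m.lift == best[0] and txt < best[1]
                ):
                    best = (m.lift, txt, cand, m)
        if best is None:
            break  # no qualifying deletion left
        _, _, cand, m = best
        current, current_metrics = cand, m
        changed = True

    if not changed:
        return rule
    clauses = _canonical(current)
    return Rule(
        clauses=clauses,
        rhs=rule.rhs,
        metrics=current_metrics,
        text=render_rule(RulePattern(clauses, rule.rhs), table),
        original_lift=original_lift,
        simplified_from=rule.text,
    )


def mine(table: DataTable, pattern: RulePattern, config: SearchConfig) -> list[Rule]:
    """Run the full search: one job per permitted RHS equality, merged.

    Jobs are independent; results are simplified, de-duplicated (rules
    identical after simplification count once), sorted by lift then support
    descending then rule text, and truncated to ``max_rules``. The output is
    a pure function of (table, pattern, config) and does not depend on the
    ``jobs`` setting, which only describes how a parallel runner may
    partition the job list.
    """
    config.validate()
    if not pattern.is_all_blank:
        raise ConfigError("mining requires a pattern whose slots are all blanks")
    if table.n_columns < 2:
        raise ConfigError("mining needs at least two columns")
    sizes = pattern.clause_sizes()
    lhs_cols = _resolve_columns(table, config.lhs_columns, "LHS")
    jobs = rhs_candidates(table, config)
    log.info("created %d jobs (one per RHS equality)", len(jobs))

    space_cache: dict[int, _SearchSpace] = {}
    collected: list[Rule] = []
    for jobno, rhs_eq in enumerate(jobs, start=1):
        cols = tuple(c for c in lhs_cols if c != rhs_eq.column)
        if not cols:
            continue
        key = hash(cols)
        if key not in space_cache:
            space_cache[key] = _build_space(
                table, cols, sizes, config.max_value_set_size
            )
        space = space_cache[key]
        found = 0
        for rule in fill_pattern(table, pattern, rhs_eq, config, _space=space):
            collected.append(simplify(rule, table, config))
            found += 1
        log.info(
            "job %d/%d (%s): %d rules", jobno, len(jobs),
            rhs_eq.render(table), found,
        )
    pruned = sum(s.pruned_branches for s in space_cache.values())
    log.info("search finished: %d raw rules, %d branches pruned",
             len(collected), pruned)

    collected.sort(key=Rule.sort_key)
    seen: set[str] = set()
    unique: list[Rule] = []
    for rule in collected:
        if rule.text in seen:
            continue
        seen.add(rule.text)
        unique.append(rule)
    if config.max_rules is not None:
        unique = unique[: config.max_rules]
    return unique
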