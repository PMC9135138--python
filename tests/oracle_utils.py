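"""Independent oracles for the test suite.

Everything here works on plain Python rows/sets (csv module, per-row scans,
itertools enumeration) and never touches the package's bitmask path, so it
can serve as ground truth for the word-parallel engine and the pruned miner.
"""

from __future__ import annotations

import csv
import io
import random
from itertools import combinations, product


def naive_parse(text):
    """(column names, rows as lists of value-or-None) via the csv module."""
    header = text.splitlines()[0]
    delim = ";" if header.count(";") > header.count(",") else ","
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    rows = list(reader)
    names = [n.strip() for n in rows[0]]
    data = []
    for raw in rows[1:]:
        if not any(c.strip() for c in raw) and raw != [""] * len(names):
            continue
        data.append([(c.strip()[0] if c.strip() else None) for c in raw])
    return names, data


def naive_rowset(rows, column, values):
    """Row indices where ``column`` holds one of ``values`` (per-row scan)."""
    vs = set(values)
    return {i for i, row in enumerate(rows) if row[column] in vs}


def naive_eval(rows, clauses):
    """Per-row interpreter for an AND-of-ORs expression.

    ``clauses``: iterable of iterables of (column, values) pairs.
    """
    out = set(range(len(rows)))
    for clause in clauses:
        hit = set()
        for column, values in clause:
            hit |= naive_rowset(rows, column, values)
        out &= hit
    return out


def naive_metrics(lhs_set, rhs_set, n):
    """(support, lhs, rhs, confidence, lift, leverage) or None."""
    lhs, rhs = len(lhs_set), len(rhs_set)
    if lhs == 0 or rhs == 0:
        return None
    s = len(lhs_set & rhs_set)
    return (
        s,
        lhs,
        rhs,
        s / lhs,
        s * n / (lhs * rhs),
        s / n - (lhs / n) * (rhs / n),
    )


def enumerate_value_sets(domain, max_size):
    """Canonical candidate value sets: non-empty subsets up to max_size,
    excluding the full domain of a multi-valued column."""
    dom = sorted(domain)
    out = []
    for size in range(1, min(max_size, len(dom)) + 1):
        if size == len(dom) >= 2:
            continue
        out.extend(combinations(dom, size))
    return out


def exhaustive_rules(rows, names, clause_sizes, rhs_col, rhs_values, config):
    """Unpruned enumerate-then-filter mining for one RHS assignment.

    Mirrors the miner's canonicalization (distinct columns per clause,
    increasing slot order, non-decreasing order across equal-width clauses,
    RHS column banned from the LHS) but does a full enumeration with per-row
    evaluation and post-hoc threshold filtering. Returns a set of hashable
    rule descriptions with their metrics.
    """
    n = len(rows)
    domains = [sorted({r[c] for r in rows} - {None}) for c in range(len(names))]
    candidates = []  # (col, values) in canonical order
    for col in config.get("lhs_columns") or range(len(names)):
        if col == rhs_col or not domains[col]:
            continue
        for vs in enumerate_value_sets(domains[col], config["max_value_set_size"]):
            candidates.append((col, vs))

    def clause_fills(size):
        for combo in combinations(range(len(candidates)), size):
            cols = [candidates[i][0] for i in combo]
            if len(set(cols)) == size:
                yield combo

    per_clause = [list(clause_fills(s)) for s in clause_sizes]
    rhs_set = naive_rowset(rows, rhs_col, rhs_values)
    found = set()
    for assignment in product(*per_clause):
        ok = True
        last = {}
        for size, combo in zip(clause_sizes, assignment):
            if size in last and combo < last[size]:
                ok = False
                break
            last[size] = combo
        if not ok:
            continue
        clauses = [
            [candidates[i] for i in combo] for combo in assignment
        ]
        lhs_set = naive_eval(rows, clauses)
        m = naive_metrics(lhs_set, rhs_set, n)
        if m is None:
            continue
        s, lhs, rhs, conf, lift, lev = m
        if (
            s >= config["min_support"]
            and conf >= config["min_confidence"]
            and lift >= config["min_lift"]
            and lev >= config["min_leverage"]
        ):
            # canonical form: clause order is immaterial under AND
            key = tuple(sorted(tuple(cl) for cl in clauses))
            found.add((key, s, lhs, rhs))
    return found


def random_table_csv(seed, max_cols=6, max_vals=4, max_rows=64, na_prob=0.1):
    """A random single-character table in the package's CSV dialect."""
    rnd = random.Random(seed)
    n_cols = rnd.randint(2, max_cols)
    n_rows = rnd.randint(8, max_rows)
    alphabets = [
        "abcd"[: rnd.randint(2, max_vals)] for _ in range(n_cols)
    ]
    names = [f"c{i}" for i in range(n_cols)]
    lines = [",".join(names)]
    for _ in range(n_rows):
        cells = [
            "" if rnd.random() < na_prob else rnd.choice(alphabets[c])
            for c in range(n_cols)
        ]
        lines.append(",".join(cells))
    return "\n".join(lines) + "\n"
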