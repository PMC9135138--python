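"""Seeded generator of tables with planted generalized rules.

The generator realizes the planted rule's counts exactly by construction
(rows are allocated, not sampled), so the engine's metrics on the planted
rule equal the returned expectations to the last digit:

* ``coverage * n`` rows satisfy the whole LHS ("A rows");
* of those, ``confidence * coverage * n`` satisfy the RHS (the support);
* the remaining rows satisfy the RHS at exactly the background rate.

Two structural choices make the planted rule robust under mining:

1. Within the A rows, a fixed fraction (``overlap_fraction``) satisfies
   every disjunct of each multi-slot clause; the rest satisfy exactly one,
   round-robin. RHS-true rows are assigned to the exclusive-disjunct rows
   first, so the RHS rate is lower in the overlap than in the exclusive
   parts. Dropping any single disjunct then demonstrably lowers the rule's
   lift — each disjunct earns its place.
2. Non-A rows satisfy a random PROPER subset of the LHS clauses, so each
   clause individually covers extra rows whose RHS rate is only the
   background rate — dropping a whole clause also lowers lift.

Randomness (which disjunct a background row satisfies, noise cells, the
final row shuffle) comes from one numpy Generator keyed by the seed, so the
same spec and seed always produce identical bytes.
"""

from __future__ import annotations

import argparse
from dataclasses import dataclass, field

import numpy as np

from .engine import RuleMetrics
from .errors import FixtureError

#: characters used as "off" values for planted columns, in preference order
_OFF_POOL = "nopqrst0123456789"


@dataclass(frozen=True)
class PlantedRuleSpec:
    """One planted generalized rule plus the table dimensions around it.

    ``lhs`` is a tuple of clauses; each clause is a tuple of
    (column name, value tuple) pairs, ORed within a clause and ANDed across
    clauses. ``rhs`` is one (column name, value) pair. Counts derived from
    ``coverage``, ``confidence`` and ``background_rate`` must be integral.
    """

    lhs: tuple[tuple[tuple[str, tuple[str, ...]], ...], ...]
    rhs: tuple[str, str]
    confidence: float
    coverage: float
    background_rate: float
    n_rows: int
    seed: int
    n_noise_columns: int = 2
    noise_alphabet: str = "uvw"
    overlap_fraction: float = 0.25

    def counts(self) -> tuple[int, int, int]:
        """(lhs_support, support, background RHS count) — validated integral."""

        def as_count(x: float, what: str) -> int:
            r = round(x)
            if abs(x - r) > 1e-9:
                raise FixtureError(f"{what} = {x} is not an integral row count")
            return r

        n_lhs = as_count(self.coverage * self.n_rows, "coverage * n_rows")
        support = as_count(self.confidence * n_lhs, "confidence * coverage * n_rows")
        bg = as_count(
            self.background_rate * (self.n_rows - n_lhs),
            "background_rate * (n_rows - lhs rows)",
        )
        return n_lhs, support, bg

    def validate(self) -> None:
        if not 0.0 < self.coverage < 1.0:
            raise FixtureError("coverage must lie strictly between 0 and 1")
        if not 0.0 <= self.confidence <= 1.0:
            raise FixtureError("confidence must lie in [0, 1]")
        if not 0.0 <= self.background_rate <= 1.0:
            raise FixtureError("background_rate must lie in [0, 1]")
        if self.n_rows < 2:
            raise FixtureError("n_rows must be at least 2")
        cols = [name for cl in self.lhs for name, _ in cl]
        if len(set(cols)) != len(cols):
            raise FixtureError("planted LHS columns must be distinct")
        if self.rhs[0] in cols:
            raise FixtureError("the RHS column may not appear on the LHS")
        for cl in self.lhs:
            if not cl:
                raise FixtureError("empty planted clause")
            for _, values in cl:
                if not values:
                    raise FixtureError("empty planted value set")
        self.counts()


@dataclass(frozen=True)
class GeneratedFixture:
    """A generated table plus everything a test needs to check it."""

    csv: str
    expected: RuleMetrics
    rule_text: str
    column_names: tuple[str, ...]
    spec: PlantedRuleSpec = field(repr=False)


def _off_values(on: tuple[str, ...]) -> list[str]:
    offs = [c for c in _OFF_POOL if c not in on]
    if len(offs) < 1:
        raise FixtureError("no off-value characters left for a planted column")
    return offs[:2]


def expected_metrics(spec: PlantedRuleSpec) -> RuleMetrics:
    """The planted rule's metrics, from the spec's exact counts."""
    n = spec.n_rows
    n_lhs, support, bg = spec.counts()
    rhs_support = support + bg
    confidence = support / n_lhs
    lift = (support * n) / (n_lhs * rhs_support)
    leverage = support / n - (n_lhs / n) * (rhs_support / n)
    return RuleMetrics(support, n_lhs, rhs_support, confidence, lift, leverage)


def planted_rule_text(spec: PlantedRuleSpec) -> str:
    """Canonical rendering of the planted rule (matches the miner's output)."""
    parts = []
    for cl in spec.lhs:
        eqs = sorted((name, "".join(sorted(values))) for name, values in cl)
        body = " OR ".join(f"{name}={vals}" for name, vals in eqs)
        parts.append(f"({body})" if len(eqs) > 1 else body)
    rhs_name, rhs_value = spec.rhs
    return f"{' AND '.join(parts)} -> {rhs_name}={rhs_value}"


def generate_table(spec: PlantedRuleSpec) -> GeneratedFixture:
    """Emit a CSV table realizing the spec exactly, plus expected metrics."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rows
    n_lhs, support, bg = spec.counts()
    n_bg = n - n_lhs

    lhs_cols = [(name, tuple(sorted(values))) for cl in spec.lhs for name, values in cl]
    rhs_name, rhs_value = spec.rhs
    names = (
        [name for name, _ in lhs_cols]
        + [rhs_name]
        + [f"noise{i + 1}" for i in range(spec.n_noise_columns)]
    )
    if len(set(names)) != len(names):
        raise FixtureError("column names (including noise columns) must be unique")

    col_of = {name: i for i, name in enumerate(names)}
    on_of = dict(lhs_cols)
    off_of = {name: _off_values(values) for name, values in lhs_cols}
    rhs_off = _off_values((rhs_value,))[0]

    grid: list[list[str]] = []

    # --- rows satisfying the whole LHS ------------------------------------
    overlap = round(spec.overlap_fraction * n_lhs)
    for pos in range(n_lhs):
        row = [""] * len(names)
        for cl in spec.lhs:
            k = len(cl)
            if k == 1 or pos < overlap:
                sat = set(range(k))
            else:
                sat = {(pos - overlap) % k}
            for slot_idx, (name, values) in enumerate(cl):
                if slot_idx in sat:
                    row[col_of[name]] = values[pos % len(values)]
                else:
                    offs = off_of[name]
                    row[col_of[name]] = offs[pos % len(offs)]
        # RHS-true rows fill from the tail: exclusive-disjunct rows first,
        # overlap rows only on overflow (keeps every disjunct lift-bearing)
        row[col_of[rhs_name]] = rhs_value if pos >= n_lhs - support else rhs_off
        grid.append(row)

    # --- background rows: a random proper subset of clauses holds ---------
    n_clauses = len(spec.lhs)
    rhs_true_bg = set(rng.choice(n_bg, size=bg, replace=False).tolist()) if bg else set()
    for pos in range(n_bg):
        row = [""] * len(names)
        while True:
            sat_clauses = [bool(rng.integers(2)) for _ in range(n_clauses)]
            if not all(sat_clauses):
                break
        for ci, cl in enumerate(spec.lhs):
            k = len(cl)
            chosen = int(rng.integers(k)) if sat_clauses[ci] else -1
            for slot_idx, (name, values) in enumerate(cl):
                if slot_idx == chosen:
                    row[col_of[name]] = values[int(rng.integers(len(values)))]
                else:
                    offs = off_of[name]
                    row[col_of[name]] = offs[int(rng.integers(len(offs)))]
        row[col_of[rhs_name]] = rhs_value if pos in rhs_true_bg else rhs_off
        grid.append(row)

    # --- noise columns and final shuffle ----------------------------------
    alphabet = list(spec.noise_alphabet)
    for row in grid:
        for i in range(spec.n_noise_columns):
            row[col_of[f"noise{i + 1}"]] = alphabet[int(rng.integers(len(alphabet)))]
    order = rng.permutation(n)
    lines = [",".join(names)] + [",".join(grid[i]) for i in order]
    csv_text = "\n".join(lines) + "\n"

    return GeneratedFixture(
        csv=csv_text,
        expected=expected_metrics(spec),
        rule_text=planted_rule_text(spec),
        column_names=tuple(names),
        spec=spec,
    )


def generate_na_noise(spec: PlantedRuleSpec, na_rate: float, seed: int) -> str:
    """The spec's table with noise-column cells independently blanked.

    Only cells of the filler noise columns are blanked (probability
    ``na_rate`` each, under ``seed``), so the planted rule's expected metrics
    still hold exactly.
    """
    if not 0.0 <= na_rate < 1.0:
        raise FixtureError("na_rate must lie in [0, 1)")
    fixture = generate_table(spec)
    if na_rate == 0.0:
        return fixture.csv
    rng = np.random.default_rng(seed)
    lines = fixture.csv.splitlines()
    names = lines[0].split(",")
    noise_idx = {i for i, name in enumerate(names) if name.startswith("noise")}
    out = [lines[0]]
    for line in lines[1:]:
        cells = line.split(",")
        for i in noise_idx:
            if rng.random() < na_rate:
                cells[i] = ""
        out.append(",".join(cells))
    return "\n".join(out) + "\n"


def default_spec(
    seed: int,
    n_rows: int = 100,
    confidence: float = 0.9,
    coverage: float = 0.4,
    background_rate: float = 0.05,
) -> PlantedRuleSpec:
    """The stock fixture: x=a AND (y=b OR z=c) -> w=d planted at high lift.

    The nominal rates are snapped to the nearest exactly realizable counts
    for the requested table size, so any ``n_rows`` is valid.
    """
    n_lhs = max(1, min(n_rows - 1, round(coverage * n_rows)))
    support = round(confidence * n_lhs)
    bg = round(background_rate * (n_rows - n_lhs))
    return PlantedRuleSpec(
        lhs=((("x", ("a",)),), (("y", ("b",)), ("z", ("c",)))),
        rhs=("w", "d"),
        confidence=support / n_lhs,
        coverage=n_lhs / n_rows,
        background_rate=bg / (n_rows - n_lhs),
        n_rows=n_rows,
        seed=seed,
    )


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(
        prog="python -m garm.synthetic",
        description="Write a synthetic table with a planted generalized rule.",
    )
    parser.add_argument("--seed", type=int, required=True)
    parser.add_argument("--n-rows", type=int, default=100)
    parser.add_argument("--na-rate", type=float, default=0.0)
    parser.add_argument("--out", required=True, help="output CSV path")
    args = parser.parse_args(argv)
    spec = default_spec(args.seed, args.n_rows)
    if args.na_rate:
        csv_text = generate_na_noise(spec, args.na_rate, args.seed + 1)
    else:
        csv_text = generate_table(spec).csv
    with open(args.out, "w", encoding="utf-8") as fh:
        fh.write(csv_text)
    print(f"wrote {args.out}: planted rule {planted_rule_text(spec)}")
    return 0


if __name__ == "__main__":  # pragma: no cover
    raise SystemExit(main())
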