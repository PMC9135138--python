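# Methods

## Model and search procedure

garm mines *generalized association rules* over a categorical table of N
rows. A rule is `C1 AND C2 AND ... AND Ck -> R`, where each LHS clause `Ci`
is a disjunction of elementary equalities (column ∈ value-set over the
column's observed single-character domain) and the RHS `R` is a single
elementary equality. The user supplies the rule *pattern* — the clause
structure with blanks — and the miner enumerates all fillings.

Scoring uses the standard frequency measures: support `N·Pr(L∧R)`,
confidence `Pr(R|L)`, lift `Pr(L∧R)/(Pr(L)Pr(R))` and leverage
`Pr(L∧R) − Pr(L)Pr(R)`. All four thresholds are inclusive. N is always the
full row count: a row with N/A in a referenced column simply fails the
equality, rather than being excluded from the denominator. The alternative
(per-rule complete-case N) would change lift on sparse tables; the global-N
convention keeps every rule's metrics comparable on one scale.
Rules whose LHS or RHS holds on zero rows carry no evidence and are
silently discarded rather than reported with undefined ratios.

### Candidate enumeration

For each column the candidate value sets are all non-empty subsets of its
observed domain up to `max_value_set_size` (default 2), excluding the full
domain of a multi-valued column, which is a tautology. The cap exists
because unrestricted subset enumeration is exponential in the domain size;
size-2 sets already express "either of these two levels" (e.g. `age=AB`),
which is the typical use. RHS candidates are singletons by default
(`rhs_singleton_only`), matching the usual "predict one outcome level"
reading; both knobs are configurable.

Commutativity of AND/OR would otherwise multiply every rule by the number
of orderings, so enumeration is canonicalized: within a clause, slots are
filled in strictly increasing (column, value-set) order with distinct
columns; across clauses of equal width, fillings are non-decreasing. A
column may still appear in two different clauses (`x=a AND (x=b OR y=c)`),
which is expressible and occasionally meaningful; contradictory repeats die
at the support bound. The RHS column is excluded from the LHS outright.
Finally, emitted clause lists are sorted into a canonical order, so two
rules that differ only by clause order share one rendering — the rendering
is the de-duplication key.

### Pruning

The search fills clauses left to right. At any prefix, the support of every
completion is bounded above by the intersection of the already-filled
clauses' row sets with the RHS row set (further clauses only shrink it);
when that bound drops below `min_support` the branch is abandoned. The
bound is sound — no threshold-passing rule can be lost — and tight at the
leaves, where it *is* the support. The test suite checks equivalence with
an unpruned enumerate-then-filter oracle on random tables.

### Job structure

Each permitted RHS equality defines one independent job (its LHS search
shares nothing with other jobs). Results are merged, de-duplicated, sorted
by lift, then support (both descending), then rule text, and truncated to
`max_rules`. The `jobs` parameter describes how a parallel runner may
partition the job list; the merge is order-independent, so output is
byte-identical for any job count. The bundled runner executes jobs
sequentially — the contract is the partition and determinism, not a thread
implementation.

### Bit-parallel evaluation

Every (column, value) pair owns a bitmask over rows; an equality is an OR
of value masks, a clause an OR of equality masks, the LHS an AND across
clauses, and metrics come from popcounts. Masks live in arbitrary-precision
Python integers, whose bitwise operations and `bit_count` run in C over
whole machine words — 64 rows per word, with no per-row Python loop. A
naive per-row interpreter exists in the test suite as the independent
oracle for this path.

### Simplification

The user's pattern is the *most complex* shape returned; survivors are
greedily reduced. Candidate deletions are (a) a whole clause, while more
than one remains, and (b) one disjunct of a multi-slot clause. A deletion
*qualifies* if the reduced rule still passes all thresholds and its lift is
at least `(1 − simplify_tolerance)` times the **original** rule's lift
(default tolerance 0.02). At each step the qualifying deletion with the
highest resulting lift is applied, ties broken toward the textually smaller
rule; the loop stops when no deletion qualifies. Design notes:

- The tolerance is anchored to the original rule's lift, not the previous
  step's: step-relative anchoring would let lift decay geometrically over
  many steps with no overall floor.
- The tolerance is relative (2% of lift), not 2 lift-points — a 2-point
  drop would be enormous for typical lifts near 1.
- Deletions that *raise* lift are always taken first, so a simplified rule
  can end up strictly better than the submitted shape. This also means the
  greedy path can keep a clause a human would call noise, when one of its
  sub-disjunctions spuriously boosts lift on the sample; the floor
  guarantee (final lift ≥ 98% of original) holds regardless.
- Two survivors that simplify to the same rule count once.

## Synthetic fixture generator

`garm.synthetic` plants a known generalized rule in a table by exact
construction rather than sampling: exactly `coverage·n` rows satisfy the
whole LHS, exactly `confidence·coverage·n` of those satisfy the RHS, and
the remaining rows carry the RHS at exactly `background_rate`. Products
that are not whole numbers are an error, so the planted rule's metrics are
known in closed form and the engine must reproduce them to the last digit.
The stock fixture (`default_spec`) plants `x=a AND (y=b OR z=c) -> w=d` in
a 100-row table with confidence 0.9, coverage 0.4 and background rate 0.05
— rates chosen so the planted rule is strong but not degenerate (lift ≈
2.3 against 5% background), with two uniform-noise columns as distractors;
for other table sizes the nominal rates snap to the nearest exactly
realizable counts.

Two structural choices make the planted rule the *uniquely best* answer,
not just a present one:

- Within the LHS rows, 25% (`overlap_fraction`) satisfy every disjunct of
  each multi-slot clause and the rest exactly one, and RHS-true rows are
  allocated to the exclusive-disjunct rows first. The RHS rate is then
  lower in the overlap than in the exclusive parts, which makes the union
  strictly better than either disjunct alone — deleting any disjunct drops
  lift, so the generalized form survives simplification.
- Rows outside the LHS satisfy a random *proper* subset of the clauses, so
  every clause individually covers extra rows at only the background RHS
  rate — deleting a whole clause also drops lift.

What the generator does **not** emulate about real clinical tables:
correlated attributes, structured (non-random) missingness, rare-category
imbalance, and many more columns than rules. Passing the recovery tests
therefore shows the algorithm is correct and well-ranked under its own
assumptions, not that real-data mining is free of spurious rules —
threshold choice still governs that. N/A injection (`generate_na_noise`)
blanks only filler-column cells, leaving planted metrics intact while
exercising the N/A semantics end to end.

## Numerical and format choices

- Metrics are IEEE doubles computed from integer counts; the identity
  `lift = confidence · N / rhs_support` is asserted internally on every
  computed metric block.
- Reports print fractional metrics to 4 decimals with half-even rounding;
  TXT and XML are rendered fully in memory before any file is opened, so a
  failing run leaves no partial output. Wall-clock timing goes to the log
  stream only, keeping files byte-reproducible.
- The CSV delimiter (comma vs semicolon) is chosen by majority count in
  the header line; cells are whitespace-stripped before the first-character
  truncation; ragged rows are a hard error (padding would silently invent
  N/A values); no quoting is honored, since single-character cells cannot
  contain a delimiter.
- Columns that are entirely N/A are kept in the table but excluded from
  enumeration; an equality over such a column evaluates to the empty set.
- Mining requires an all-blank pattern; filled rule expressions parse and
  render (for round-tripping reports) but are not mining templates.

## Problem sizes in the test suite

Oracle-equivalence checks run on 200 random tables up to 6 columns × 4
values × 64 rows — small enough that the unpruned exhaustive oracle stays
honest, large enough to exercise multi-word masks (>64 rows never changes
the code path, which is word-count agnostic). Recovery and simplification
suites use 100-row fixtures (50 and 100 seeds respectively); the whole
suite and the acceptance script each complete in a few minutes on one core.

## Known limitations

- Value-set enumeration beyond size 2 grows combinatorially; raising
  `max_value_set_size` on wide-domain columns can explode the search.
- Simplification is greedy hill-climbing over deletions; it does not
  explore deletion orders and can stop at a local optimum (and, as noted,
  can retain a spuriously helpful sub-disjunction).
- Logically equivalent but textually different LHSs over the *same* column
  (e.g. `x=an AND x=no` vs `x=n`) are distinct rules; no semantic
  equivalence reduction is attempted beyond clause-order canonicalization.
- The miner materializes per-candidate masks and clause combinations up
  front; tables with hundreds of columns and permissive thresholds are
  better attacked with column constraints (`lhs_columns`/`rhs_columns`).
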