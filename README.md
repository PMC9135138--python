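# garm — generalized association rule mining for categorical tables

Large clinical and biological studies produce wide categorical tables —
thousands of subjects, hundreds of discretized attributes, plenty of missing
entries. Association rule mining automates the search for multi-parametric
relations in such tables (for example, candidate combinatorial biomarkers:
"patients with attributes *a* and *b* tend to have condition *y*"). Classical
rules are pure conjunctions, `a AND b AND ... -> y`. **garm** mines
*generalized* rules whose left-hand side is a conjunction of disjunctions:

```
age=AB AND (bread=y OR onions=n) -> butter=y
```

A single AND-of-ORs rule compresses many conjunctive rules — a left-hand
side `(a OR b) AND (c OR d) AND (e OR f)` is equivalent to the OR of eight
ternary conjunctions — so result lists stay human-readable.

## The statistics

For a table of *N* rows, each candidate rule LHS → RHS is scored by

- **support** — number of rows where LHS and RHS both hold
  (`supp = N · Pr(LHS ∧ RHS)`), with LHS support and RHS support defined
  analogously per side;
- **confidence** — `supp / supp(LHS)`, the empirical conditional frequency
  of the RHS given the LHS;
- **lift** — `Pr(LHS ∧ RHS) / (Pr(LHS) · Pr(RHS))`; 1 when the sides are
  independent, above 1 when the LHS raises the RHS's frequency;
- **leverage** — `Pr(LHS ∧ RHS) − Pr(LHS) · Pr(RHS)` (Piatetsky–Shapiro);
  0 under independence.

Rules must clear user thresholds on all four. The search fills every blank
of a user-supplied rule pattern (e.g. `_ AND (_ OR _) -> _`) with
*elementary equalities* — predicates of the form `column ∈ {values}` over
the single-character value domains — and prunes branches whose best
achievable support already falls below the threshold. Boolean evaluation is
bit-parallel: each (column, value) pair owns a row bitmask, so 64 rows are
processed per machine word. Surviving rules are then *simplified*: LHS
clauses and disjuncts are greedily deleted as long as the rule's lift does
not fall more than 2% (configurable) below the original rule's lift, so the
reported rules are no more complex than the data justifies.

## Input format

A comma- or semicolon-separated CSV whose first line holds column names and
whose cells are single printable ASCII characters (longer cells are
truncated to their first character; an empty cell is N/A and satisfies no
equality; different characters are different values). Attributes must
arrive pre-discretized, e.g. age groups coded `A`, `B`, `C`.

## Worked example

Generate a 100-row table with a planted rule and mine it:

```
python -m garm.synthetic --seed 11 --out example.csv
garm --in example.csv --pattern "_ AND (_ OR _) -> _" \
     --min-support 15 --min-confidence 0.7 --min-lift 1.5 \
     --rhs-columns w --max-rules 5
```

prints

```
# garm association rule mining report
# input: example.csv
# pattern: _ AND (_ OR _) -> _
# rows: 100
# columns: 6
# min_support: 15
# min_confidence: 0.7000
# min_lift: 1.5000
# min_leverage: -0.2500
# max_value_set_size: 2
# simplify_tolerance: 0.0200
# rules: 5
# fields: rule	support	lhs_support	rhs_support	confidence	lift	leverage
x=a AND (y=b OR z=c) -> w=d	36	40	39	0.9000	2.3077	0.2040
x=a AND y=b -> w=d	21	25	39	0.8400	2.1538	0.1125
x=a AND z=c -> w=d	21	25	39	0.8400	2.1538	0.1125
y=b AND z=n -> w=d	16	20	39	0.8000	2.0513	0.0820
x=ao AND (y=b OR z=c) -> w=d	37	48	39	0.7708	1.9765	0.1828
```

The planted rule ranks first: 40 of 100 rows satisfy its LHS, 36 of those
also satisfy `w=d`, giving confidence 0.90; since only 39 rows satisfy
`w=d` overall, the LHS raises the RHS frequency 2.31-fold (lift), and the
joint frequency exceeds the independence prediction by 0.204 (leverage).
The runner-up rules are the planted rule's own conjunctive fragments, at
visibly lower lift. `--xml out.xml` writes the same report as structured
XML; `--jobs` controls how the search may be partitioned (one independent
job per right-hand-side equality) without affecting the output bytes.

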