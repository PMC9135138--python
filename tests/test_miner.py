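import random
from itertools import product

import pytest

from garm import (
    ConfigError,
    Equality,
    SearchConfig,
    enumerate_equalities,
    equality_rowset,
    fill_pattern,
    mine,
    parse_pattern,
    parse_table,
    simplify,
    support_upper_bound,
)
from garm.miner import rhs_candidates
from garm.synthetic import default_spec, generate_table

from oracle_utils import exhaustive_rules, naive_parse


def _values(eqs):
    return {e.values for e in eqs}


class TestEnumerateEqualities:
    def test_full_domain_excluded(self):
        t = parse_table("x\nA\nB\n")
        assert _values(enumerate_equalities(t, 0, 2)) == {("A",), ("B",)}

    def test_singleton_domain_kept(self):
        t = parse_table("x,y\ny,1\ny,2\n")
        assert _values(enumerate_equalities(t, 0, 2)) == {("y",)}

    def test_three_value_domain_pairs(self):
        t = parse_table("x\nA\nB\nC\n")
        got = [e.values for e in enumerate_equalities(t, 0, 2)]
        assert got == [
            ("A",), ("B",), ("C",), ("A", "B"), ("A", "C"), ("B", "C"),
        ]  # canonical: singletons first, then pairs in character order

    def test_size_cap_respected(self):
        t = parse_table("x\nA\nB\nC\nD\n")
        assert all(
            len(e.values) <= 1 for e in enumerate_equalities(t, 0, 1)
        )


class TestSupportUpperBound:
    @pytest.fixture
    def table(self):
        return parse_table(generate_table(default_spec(3, 60)).csv)

    def test_nothing_assigned_gives_rhs_support(self, table):
        rhs = equality_rowset(table, Equality(table.column("w").index, ("d",)))
        partial = [[None], [None, None]]
        assert support_upper_bound(table, partial, rhs) == rhs.cardinality

    def test_tight_at_the_leaf(self, table):
        xi = table.column("x").index
        yi = table.column("y").index
        zi = table.column("z").index
        rhs = equality_rowset(table, Equality(table.column("w").index, ("d",)))
        clauses = [
            [Equality(xi, ("a",))],
            [Equality(yi, ("b",)), Equality(zi, ("c",))],
        ]
        lhs = equality_rowset(table, clauses[0][0]) & (
            equality_rowset(table, clauses[1][0])
            | equality_rowset(table, clauses[1][1])
        )
        assert support_upper_bound(table, clauses, rhs) == (lhs & rhs).cardinality

    @pytest.mark.parametrize("seed", range(25))
    def test_bound_dominates_every_completion(self, seed):
        """On random partial fills, the bound >= the exact support of every
        completion (exhaustively enumerated on a small table)."""
        rnd = random.Random(seed)
        fixture = generate_table(default_spec(seed, 40))
        t = parse_table(fixture.csv)
        rhs_eq = Equality(t.column("w").index, ("d",))
        rhs = equality_rowset(t, rhs_eq)
        pool = [
            eq
            for c in t.usable_columns()
            if c != rhs_eq.column
            for eq in enumerate_equalities(t, c, 2)
        ]
        # two clauses: first fixed, second left open
        first = [rnd.choice(pool)]
        partial = [first, [None]]
        bound = support_upper_bound(t, partial, rhs)
        first_rows = equality_rowset(t, first[0])
        for completion in pool:
            lhs = first_rows & equality_rowset(t, completion)
            assert bound >= (lhs & rhs).cardinality


class TestFillPattern:
    def test_unsatisfiable_support_threshold_yields_nothing(self):
        fixture = generate_table(default_spec(1, 50))
        t = parse_table(fixture.csv)
        cfg = SearchConfig(min_support=t.n_rows + 1)
        rules = list(
            fill_pattern(
                t,
                parse_pattern("_ -> _"),
                Equality(t.column("w").index, ("d",)),
                cfg,
            )
        )
        assert rules == []

    def test_planted_rule_among_the_yield(self):
        fixture = generate_table(default_spec(5, 100))
        t = parse_table(fixture.csv)
        cfg = SearchConfig(min_support=10, min_confidence=0.5, min_lift=1.1)
        rules = list(
            fill_pattern(
                t,
                parse_pattern("_ AND (_ OR _) -> _"),
                Equality(t.column("w").index, ("d",)),
                cfg,
            )
        )
        assert fixture.rule_text in {r.text for r in rules}

    def test_rules_unique_and_lhs_avoids_rhs_column(self):
        fixture = generate_table(default_spec(2, 80))
        t = parse_table(fixture.csv)
        rhs_eq = Equality(t.column("w").index, ("d",))
        cfg = SearchConfig(min_support=4)
        rules = list(
            fill_pattern(t, parse_pattern("_ AND _ -> _"), rhs_eq, cfg)
        )
        texts = [r.text for r in rules]
        assert len(texts) == len(set(texts))
        for r in rules:
            assert all(e.column != rhs_eq.column for cl in r.clauses for e in cl)

    @pytest.mark.parametrize("seed", range(15))
    @pytest.mark.parametrize("pattern_text", ["_ AND _ -> _", "(_ OR _) -> _"])
    def test_pruned_search_equals_exhaustive_filter(self, seed, pattern_text):
        """Branch-and-bound yields exactly the enumerate-then-filter rules."""
        from oracle_utils import random_table_csv

        csv_text = random_table_csv(seed, max_cols=5, max_vals=3, max_rows=40)
        t = parse_table(csv_text)
        names, rows = naive_parse(csv_text)
        pattern = parse_pattern(pattern_text)
        cfg = SearchConfig(min_support=3, min_confidence=0.4, min_lift=1.05)
        oracle_cfg = {
            "min_support": 3, "min_confidence": 0.4, "min_lift": 1.05,
            "min_leverage": -0.25, "max_value_set_size": 2, "lhs_columns": None,
        }
        for rhs_eq in rhs_candidates(t, cfg):
            got = {
                (
                    tuple(tuple((e.column, e.values) for e in cl) for cl in r.clauses),
                    r.metrics.support,
                    r.metrics.lhs_support,
                    r.metrics.rhs_support,
                )
                for r in fill_pattern(t, pattern, rhs_eq, cfg)
            }
            want = exhaustive_rules(
                rows, names, pattern.clause_sizes(), rhs_eq.column,
                rhs_eq.values, oracle_cfg,
            )
            assert got == want


class TestSimplify:
    def _mk_rule(self, t, clauses, rhs_eq, cfg):
        from garm.engine import compute_metrics, evaluate_expression
        from garm.miner import Rule
        from garm.pattern import RulePattern, render_rule

        lhs = evaluate_expression(t, clauses)
        rhs = equality_rowset(t, rhs_eq)
        m = compute_metrics(lhs, rhs, t.n_rows)
        return Rule(
            clauses=clauses,
            rhs=rhs_eq,
            metrics=m,
            text=render_rule(RulePattern(clauses, rhs_eq), t),
            original_lift=m.lift,
        )

    def test_redundant_conjunct_removed(self):
        """A clause satisfied by every row leaves lift unchanged when deleted."""
        rows = ["x,f,y"]
        for i in range(40):
            rows.append(f"{'a' if i < 12 else 'b'},t,{'c' if i < 10 else 'd'}")
        t = parse_table("\n".join(rows) + "\n")
        cfg = SearchConfig(min_support=2, simplify_tolerance=0.02)
        clauses = ((Equality(0, ("a",)),), (Equality(1, ("t",)),))
        rule = self._mk_rule(t, clauses, Equality(2, ("c",)), cfg)
        out = simplify(rule, t, cfg)
        assert out.text == "x=a -> y=c"
        assert out.metrics.lift == rule.metrics.lift
        assert out.simplified_from == rule.text

    def test_zero_tolerance_keeps_informative_clauses(self):
        fixture = generate_table(default_spec(11, 100))
        t = parse_table(fixture.csv)
        cfg = SearchConfig(min_support=5, simplify_tolerance=0.0)
        pat = parse_pattern(fixture.rule_text, t)
        rule = self._mk_rule(
            t, pat.lhs_clauses, pat.rhs, cfg
        )
        assert simplify(rule, t, cfg).text == rule.text

    @pytest.mark.parametrize("seed", range(10))
    def test_noise_clause_deleted_and_lift_floor_respected(self, seed):
        """Appending an uninformative always-true clause to the planted rule
        gets simplified away; the result keeps >= 98% of the original lift."""
        fixture = generate_table(default_spec(seed, 100))
        # add a constant column: its single equality is true on every row
        lines = fixture.csv.splitlines()
        lines[0] += ",f"
        for i in range(1, len(lines)):
            lines[i] += ",t"
        t = parse_table("\n".join(lines) + "\n")
        cfg = SearchConfig(min_support=5)
        pat = parse_pattern(fixture.rule_text, t)
        noise_ci = t.column("f").index
        clauses = pat.lhs_clauses + ((Equality(noise_ci, ("t",)),),)
        rule = self._mk_rule(t, clauses, pat.rhs, cfg)
        out = simplify(rule, t, cfg)
        assert all(e.column != noise_ci for cl in out.clauses for e in cl)
        assert out.text == fixture.rule_text
        assert out.metrics.lift >= 0.98 * rule.metrics.lift

    def test_greedy_deletion_may_climb_to_higher_lift(self):
        """Deletions that raise lift are preferred, so a simplified rule can
        end up strictly better than the original."""
        fixture = generate_table(default_spec(0, 100))
        t = parse_table(fixture.csv)
        cfg = SearchConfig(min_support=5)
        pat = parse_pattern(fixture.rule_text, t)
        noise_ci = t.column("noise1").index
        dom = sorted(t.columns[noise_ci].domain)
        noise_clause = tuple(Equality(noise_ci, (v,)) for v in dom)
        rule = self._mk_rule(t, pat.lhs_clauses + (noise_clause,), pat.rhs, cfg)
        out = simplify(rule, t, cfg)
        n_slots = sum(len(cl) for cl in out.clauses)
        assert n_slots < sum(len(cl) for cl in rule.clauses)
        assert out.metrics.lift >= 0.98 * rule.metrics.lift


class TestMine:
    def test_planted_generalized_rule_ranked_first(self):
        fixture = generate_table(default_spec(21, 100))
        t = parse_table(fixture.csv)
        e = fixture.expected
        cfg = SearchConfig(
            min_support=int(0.9 * e.support),
            min_confidence=0.9 * e.confidence,
            min_lift=0.9 * e.lift,
            min_leverage=0.9 * e.leverage,
        )
        rules = mine(t, parse_pattern("_ AND (_ OR _) -> _"), cfg)
        assert rules and rules[0].text == fixture.rule_text
        assert rules[0].metrics == e

    def test_job_count_is_number_of_rhs_equalities(self):
        fixture = generate_table(default_spec(4, 60))
        t = parse_table(fixture.csv)
        cfg = SearchConfig()
        expected = sum(
            len(enumerate_equalities(t, c, 1)) for c in t.usable_columns()
        )
        assert len(rhs_candidates(t, cfg)) == expected

    def test_output_invariant_under_jobs_setting(self):
        fixture = generate_table(default_spec(6, 80))
        t = parse_table(fixture.csv)
        pattern = parse_pattern("_ AND _ -> _")
        base = SearchConfig(min_support=8, min_confidence=0.5, min_lift=1.1)
        r1 = mine(t, pattern, base)
        r8 = mine(t, pattern, SearchConfig(
            min_support=8, min_confidence=0.5, min_lift=1.1, jobs=8,
        ))
        assert [(r.text, r.metrics) for r in r1] == [(r.text, r.metrics) for r in r8]

    def test_output_invariant_under_row_permutation(self):
        fixture = generate_table(default_spec(9, 60))
        lines = fixture.csv.splitlines()
        shuffled = [lines[0]] + random.Random(0).sample(lines[1:], len(lines) - 1)
        pattern = parse_pattern("_ -> _")
        cfg = SearchConfig(min_support=6, min_confidence=0.5, min_lift=1.1)
        a = mine(parse_table(fixture.csv), pattern, cfg)
        b = mine(parse_table("\n".join(shuffled) + "\n"), pattern, cfg)
        assert [(r.text, r.metrics) for r in a] == [(r.text, r.metrics) for r in b]

    def test_simplified_lift_floor_holds_for_every_emitted_rule(self):
        fixture = generate_table(default_spec(13, 100))
        t = parse_table(fixture.csv)
        cfg = SearchConfig(min_support=5, min_confidence=0.3, min_lift=1.0)
        rules = mine(t, parse_pattern("_ AND _ -> _"), cfg)
        assert rules
        for r in rules:
            assert r.metrics.lift >= (1 - cfg.simplify_tolerance) * r.original_lift

    def test_max_rules_truncates_after_sorting(self):
        fixture = generate_table(default_spec(14, 80))
        t = parse_table(fixture.csv)
        cfg_all = SearchConfig(min_support=4, min_confidence=0.3, min_lift=1.0)
        cfg_cap = SearchConfig(
            min_support=4, min_confidence=0.3, min_lift=1.0, max_rules=3
        )
        pattern = parse_pattern("_ -> _")
        assert mine(t, pattern, cfg_cap) == mine(t, pattern, cfg_all)[:3]

    def test_config_errors(self):
        fixture = generate_table(default_spec(1, 40))
        t = parse_table(fixture.csv)
        pattern = parse_pattern("_ -> _")
        with pytest.raises(ConfigError):
            mine(t, pattern, SearchConfig(min_support=0))
        with pytest.raises(ConfigError):
            mine(t, pattern, SearchConfig(rhs_columns=frozenset()))
        with pytest.raises(ConfigError):
            mine(t, pattern, SearchConfig(rhs_columns=frozenset({99})))
        filled = parse_pattern("x=a -> w=d", t)
        with pytest.raises(ConfigError):
            mine(t, filled, SearchConfig())
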