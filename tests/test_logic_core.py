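"""Unit and property tests for the propositional engine."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nhst_logic.logic_core import (
    FALSE,
    TRUE,
    And,
    EvaluationError,
    InconsistentPremisesError,
    LogicError,
    Not,
    Or,
    Var,
    disjunction_eliminate,
    disjuncts,
    entails,
    equivalent,
    evaluate,
    formula_from_json,
    formula_to_json,
    free_domain,
    is_contradiction,
    is_satisfiable,
    is_tautology,
    make_or,
    substitute,
    to_dnf,
    truth_table,
)
from tests.conftest import brute_eval, random_formula

G, J = Var("G"), Var("J")
NOT_G_AND_J = Not(And(G, J))


class TestEvaluate:
    @pytest.mark.parametrize(
        "g, j, expected",
        [(True, True, False), (True, False, True),
         (False, True, True), (False, False, True)],
    )
    def test_negated_conjunction_rows(self, g, j, expected):
        """The four classic rows of the negated-conjunction truth table."""
        assert evaluate(NOT_G_AND_J, {"G": g, "J": j}) is expected

    def test_atom_identity(self):
        assert evaluate(Var("a"), {"a": True}) is True

    def test_unknown_atom_raises(self):
        with pytest.raises(EvaluationError):
            evaluate(Var("missing"), {"a": True})

    def test_agrees_with_brute_force_on_random_formulas(self):
        rng = random.Random(20240917)
        domain = free_domain(list("abcdef"))
        for _ in range(300):
            f = random_formula(rng, list("abcdef"))
            ast = formula_to_json(f)
            for w in domain.worlds:
                assert evaluate(f, w) == brute_eval(ast, w)


class TestTruthTable:
    def test_negated_conjunction_column_pattern(self):
        """F,T,T,T down the four assignments, first atom varying slowest."""
        d = free_domain(["G", "J"])
        table = truth_table([NOT_G_AND_J], d)
        assert table.column(0) == (False, True, True, True)
        assert table.assignments == (
            (True, True), (True, False), (False, True), (False, False)
        )

    def test_single_world_domain_single_row(self):
        d = free_domain(["a"])
        sub = truth_table([Var("a")], d)
        assert len(sub.rows) == 2  # free domain over one atom has 2 worlds
        from nhst_logic.logic_core import Atom, Domain

        one = Domain(atoms=(Atom("a"),), worlds=({"a": True},))
        assert len(truth_table([Var("a")], one).rows) == 1

    def test_rows_match_per_world_evaluation(self):
        rng = random.Random(7)
        d = free_domain(list("abc"))
        fs = [random_formula(rng, list("abc")) for _ in range(4)]
        table = truth_table(fs, d)
        for i, w in enumerate(d.worlds):
            assert table.rows[i] == tuple(evaluate(f, w) for f in fs)

    def test_empty_formula_list_rejected(self):
        with pytest.raises(LogicError):
            truth_table([], free_domain(["a"]))

    def test_csv_and_text_exports(self):
        d = free_domain(["G", "J"])
        table = truth_table([NOT_G_AND_J], d, headers=["¬(G ∧ J)"])
        csv_text = table.to_csv()
        assert csv_text.splitlines()[0] == "G,J,¬(G ∧ J)"
        assert csv_text.splitlines()[1] == "T,T,F"
        assert "¬(G ∧ J)" in table.to_text()


class TestEquivalence:
    def test_negated_conjunction_equals_three_way_disjunction(self):
        d = free_domain(["G", "J"])
        dnf = Or(And(G, Not(J)), And(Not(G), J), And(Not(G), Not(J)))
        assert equivalent(NOT_G_AND_J, dnf, d)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_self_equivalence(self, seed):
        rng = random.Random(seed)
        f = random_formula(rng, list("abcd"))
        assert equivalent(f, f, free_domain(list("abcd")))

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_de_morgan(self, seed):
        """Negating a whole conjunction equals the disjunction of the
        negations — the rule guarding against negating only part of a
        hypothesis."""
        rng = random.Random(seed)
        d = free_domain(list("abcd"))
        f = random_formula(rng, list("abcd"), depth=2)
        g = random_formula(rng, list("abcd"), depth=2)
        assert equivalent(Not(And(f, g)), Or(Not(f), Not(g)), d)


class TestSatisfiability:
    def test_literal_contradiction(self):
        d = free_domain(["a"])
        assert is_contradiction(And(Var("a"), Not(Var("a"))), d)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_contradiction_satisfiability_duality(self, seed):
        rng = random.Random(seed)
        d = free_domain(list("abc"))
        f = random_formula(rng, list("abc"))
        assert is_contradiction(f, d) == (not is_satisfiable(f, d))
        assert is_tautology(f, d) == is_contradiction(Not(f), d)


class TestDnf:
    def test_single_atom_is_itself(self):
        d = free_domain(["a"])
        assert to_dnf(Var("a"), d) == Var("a")

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_dnf_equivalent_and_contradiction_free(self, seed):
        rng = random.Random(seed)
        d = free_domain(list("abcd"))
        f = random_formula(rng, list("abcd"))
        dnf = to_dnf(f, d)
        assert equivalent(f, dnf, d)
        for dj in disjuncts(dnf):
            if dnf != FALSE:
                assert is_satisfiable(dj, d)

    def test_contradictory_formula_yields_flagged_empty_disjunction(self):
        d = free_domain(["a"])
        assert to_dnf(And(Var("a"), Not(Var("a"))), d) == FALSE

    def test_dropped_minterms_recorded(self):
        """Minterms no admissible world realises are dropped and reported."""
        from nhst_logic.logic_core import Atom, Domain

        # constrained domain: b is always the negation of a
        d = Domain(
            atoms=(Atom("a"), Atom("b")),
            worlds=({"a": True, "b": False}, {"a": False, "b": True}),
        )
        dropped: list = []
        dnf = to_dnf(Or(Var("a"), Var("b")), d, dropped=dropped)
        assert dropped  # the a&b minterm is inadmissible
        assert equivalent(dnf, Or(Var("a"), Var("b")), d)


class TestSubstitute:
    def test_false_substitution_prunes_disjuncts(self):
        f = Or(Var("dead"), And(Var("a"), Var("b")))
        assert substitute(f, {"dead": False}) == And(Var("a"), Var("b"))

    def test_collapse_to_constant(self):
        assert substitute(Var("dead"), {"dead": False}) == FALSE
        assert substitute(Not(Var("dead")), {"dead": False}) == TRUE


class TestDisjunctionElimination:
    def test_single_disjunct_no_premises_is_identity(self):
        d = free_domain(["a"])
        conclusion, deriv = disjunction_eliminate(Var("a"), [], d)
        assert conclusion == Var("a")
        assert deriv.verify(d)

    def test_useless_premise_warns(self):
        d = free_domain(["a", "b"])
        dnf = Or(Var("a"), Var("b"))
        conclusion, deriv = disjunction_eliminate(dnf, [Or(Var("a"), Var("b"))], d)
        assert deriv.warnings
        assert equivalent(conclusion, dnf, d)

    def test_inconsistent_premises_raise(self):
        d = free_domain(["a", "b"])
        with pytest.raises(InconsistentPremisesError):
            disjunction_eliminate(
                Or(Var("a"), Var("b")), [Not(Var("a")), Not(Var("b"))], d
            )

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_soundness_and_exact_survivors(self, seed):
        """The conclusion is entailed by dnf+premises and is exactly the
        disjunction of the non-refuted disjuncts."""
        rng = random.Random(seed)
        atoms = list("abc")
        d = free_domain(atoms)
        f = random_formula(rng, atoms)
        dnf = to_dnf(f, d)
        if dnf == FALSE:
            return
        premise = Not(rng.choice(list(disjuncts(dnf))))
        try:
            conclusion, deriv = disjunction_eliminate(dnf, [premise], d)
        except InconsistentPremisesError:
            assert is_contradiction(And(dnf, premise), d)
            return
        assert entails([dnf, premise], conclusion, d)
        assert deriv.verify(d)
        survivors = [
            dj for dj in disjuncts(dnf) if is_satisfiable(And(premise, dj), d)
        ]
        assert conclusion == make_or(survivors)


class TestJsonRoundTrip:
    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_round_trip_stable(self, seed):
        rng = random.Random(seed)
        f = random_formula(rng, list("xyz"))
        assert formula_from_json(formula_to_json(f)) == f

    def test_bad_op_rejected(self):
        with pytest.raises(LogicError):
            formula_from_json({"op": "xor", "children": []})
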