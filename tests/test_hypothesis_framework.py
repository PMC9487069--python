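"""Tests for hypothesis construction, pair validation and derivations."""

from __future__ import annotations

import itertools

import pytest

from nhst_logic.hypothesis_framework import (
    HypothesisPair,
    PremisePackage,
    alternative_dnf,
    bias_hypothesis,
    conclude_with_premises,
    expand_alternative,
    locate_research_hypothesis,
    preset_package,
    real_alternative,
    research_hypothesis,
    testable_null,
    textbook_alternative,
    textbook_null,
    validate_pair,
)
from nhst_logic.logic_core import (
    And,
    InconsistentPremisesError,
    LogicError,
    Not,
    Or,
    disjuncts,
    entails,
    equivalent,
    is_contradiction,
    is_satisfiable,
    is_tautology,
    satisfying_worlds,
)
from nhst_logic.nhst_semantics import (
    BIAS,
    CHANCE,
    DEFAULT_UNIVERSE,
    MEANS,
    OPEN_UNIVERSE,
    TWO_CAUSE_UNIVERSE,
    WorldState,
    domain_for,
    due_alone,
    pop_eq,
    pop_neq,
)


class TestConstruction:
    def test_testable_null_structure(self):
        h0 = testable_null()
        assert h0 == And(pop_eq(), due_alone(CHANCE))

    def test_real_alternative_is_whole_negation(self):
        h0 = testable_null()
        ha = real_alternative(h0)
        assert ha == Not(h0)
        d = domain_for(DEFAULT_UNIVERSE, [h0])
        assert equivalent(real_alternative(ha), h0, d)  # double negation

    def test_any_formula_and_its_negation_partition_every_domain(self):
        d = domain_for(OPEN_UNIVERSE)
        for f in (testable_null(), research_hypothesis(), pop_eq()):
            ha = real_alternative(f)
            assert is_contradiction(And(f, ha), d)
            assert is_tautology(Or(f, ha), d)


class TestAlternativeDnf:
    def test_two_disjunct_chance_form(self):
        """Over the default universe the alternative splits into the two
        population polarities, each with the chance attribution negated."""
        dnf = alternative_dnf(MEANS, DEFAULT_UNIVERSE, "chance")
        assert disjuncts(dnf) == (
            And(pop_eq(), Not(due_alone(CHANCE))),
            And(pop_neq(), Not(due_alone(CHANCE))),
        )

    def test_three_disjunct_research_form_has_ht_last(self):
        dnf = alternative_dnf(MEANS, DEFAULT_UNIVERSE, "research")
        parts = disjuncts(dnf)
        assert len(parts) == 3
        assert parts[-1] == research_hypothesis()

    def test_contradictory_disjunct_dropped_over_closed_two_cause_model(self):
        """With only chance and the true effect as causes, the
        equal-population disjunct of the alternative has no world."""
        dropped: list = []
        dnf = alternative_dnf(MEANS, TWO_CAUSE_UNIVERSE, "chance", dropped=dropped)
        assert disjuncts(dnf) == (And(pop_neq(), Not(due_alone(CHANCE))),)
        assert dropped == [And(pop_eq(), Not(due_alone(CHANCE)))]

    @pytest.mark.parametrize("style", ["chance", "research", "bias", "bias_alone"])
    @pytest.mark.parametrize("universe", [DEFAULT_UNIVERSE, OPEN_UNIVERSE])
    def test_every_expansion_is_equivalent_to_the_negated_null(
        self, style, universe
    ):
        dnf, d = expand_alternative(universe, style)
        assert equivalent(dnf, Not(testable_null()), d)
        for dj in disjuncts(dnf):
            assert is_satisfiable(dj, d)

    def test_null_or_alternative_dnf_is_tautology(self):
        dnf = alternative_dnf(MEANS, DEFAULT_UNIVERSE, "research")
        d = domain_for(DEFAULT_UNIVERSE, [dnf])
        assert is_tautology(Or(testable_null(), dnf), d)


class TestLocateResearchHypothesis:
    def test_exact_match_in_research_form(self):
        dnf = alternative_dnf(MEANS, DEFAULT_UNIVERSE, "research")
        loc = locate_research_hypothesis(dnf, DEFAULT_UNIVERSE)
        assert loc.relation == "equal"
        assert loc.index == len(disjuncts(dnf)) - 1

    def test_containment_in_chance_form(self):
        """In the two-disjunct form H_T is strictly inside the last
        disjunct, not equal to it."""
        dnf = alternative_dnf(MEANS, DEFAULT_UNIVERSE, "chance")
        loc = locate_research_hypothesis(dnf, DEFAULT_UNIVERSE)
        assert loc.relation == "contained"
        assert loc.index == 1

    def test_not_found_in_null_dnf(self):
        with pytest.raises(LogicError):
            locate_research_hypothesis(testable_null(), DEFAULT_UNIVERSE)


class TestValidatePair:
    def _pair(self, h0, ha, u=DEFAULT_UNIVERSE):
        d = domain_for(u, [h0, ha])
        return HypothesisPair(h0, ha, MEANS, d)

    def test_real_pair_is_valid(self):
        h0 = testable_null()
        rep = validate_pair(self._pair(h0, real_alternative(h0)))
        assert rep.verdict == "valid"
        assert rep.mutually_exclusive and rep.exhaustive

    def test_research_pair_is_false_dichotomy_with_witness(self):
        rep = validate_pair(self._pair(testable_null(), research_hypothesis()))
        assert rep.verdict == "false_dichotomy"
        witness = WorldState(True, frozenset({BIAS}))
        assert witness in rep.gap_witnesses

    def test_textbook_pair_is_exclusive_and_exhaustive(self):
        rep = validate_pair(self._pair(textbook_null(), textbook_alternative()))
        assert rep.verdict == "valid"

    def test_self_pair_overlaps(self):
        f = testable_null()
        rep = validate_pair(self._pair(f, f))
        assert not rep.mutually_exclusive
        assert rep.verdict in {"overlapping", "both_defects"}
        assert rep.overlap_witnesses


class TestPremisePackages:
    def test_conclude_ht_package_reaches_exactly_ht(self):
        rep = conclude_with_premises(MEANS, None, preset_package("table3_conclude_HT"))
        assert rep.conclusion == research_hypothesis()
        assert rep.reached_intended is True
        assert len(rep.derivation.steps) == 2
        d = domain_for(rep.universe, [rep.dnf, *rep.package.premises])
        assert rep.derivation.verify(d)

    def test_no_bias_only_package_keeps_three_disjuncts(self):
        """Assuming only 'no bias' leaves a conclusion strictly wider than
        the research hypothesis."""
        rep = conclude_with_premises(
            MEANS, None, preset_package("table3_no_bias_only")
        )
        parts = disjuncts(rep.conclusion)
        assert len(parts) == 3
        assert research_hypothesis() in parts
        assert rep.reached_intended is True
        d = domain_for(rep.universe, [rep.conclusion])
        assert not equivalent(rep.conclusion, research_hypothesis(), d)

    def test_conclude_hb_package_reaches_bias_hypothesis(self):
        rep = conclude_with_premises(MEANS, None, preset_package("table3_conclude_HB"))
        assert rep.conclusion == bias_hypothesis()
        assert rep.reached_intended is True

    def test_minimum_axiom_set_concludes_the_whole_alternative(self):
        rep = conclude_with_premises(MEANS, None, preset_package("minimum_axiom_set"))
        d = domain_for(rep.universe, [rep.conclusion, testable_null()])
        assert equivalent(rep.conclusion, Not(testable_null()), d)

    def test_conclusion_entailed_and_ht_implies_it(self):
        for name in ("table3_conclude_HT", "table3_no_bias_only"):
            pkg = preset_package(name)
            rep = conclude_with_premises(MEANS, None, pkg)
            d = domain_for(rep.universe, [rep.dnf, rep.conclusion, *pkg.premises])
            assert entails([rep.dnf, *pkg.premises], rep.conclusion, d)
            if research_hypothesis() in disjuncts(rep.conclusion) or (
                rep.conclusion == research_hypothesis()
            ):
                assert entails([research_hypothesis()], rep.conclusion, d)

    def test_premise_order_commutes(self):
        pkg = preset_package("table3_conclude_HT")
        conclusions = []
        for perm in itertools.permutations(pkg.premises):
            swapped = PremisePackage(
                name=pkg.name,
                premises=perm,
                intended_conclusion=pkg.intended_conclusion,
                expansion=pkg.expansion,
            )
            conclusions.append(
                conclude_with_premises(MEANS, None, swapped).conclusion
            )
        assert all(c == conclusions[0] for c in conclusions)

    def test_adding_premises_never_enlarges_the_conclusion(self):
        """Monotonicity: each extra premise weakly shrinks the set of
        worlds satisfying the conclusion."""
        pkg = preset_package("table3_conclude_HT")
        prev = None
        for k in range(len(pkg.premises) + 1):
            partial = PremisePackage(
                name="minimum_axiom_set" if k == 0 else f"partial_{k}",
                premises=pkg.premises[:k],
                expansion=pkg.expansion,
            )
            rep = conclude_with_premises(MEANS, None, partial)
            d = domain_for(rep.universe, [rep.conclusion])
            worlds = set(satisfying_worlds(rep.conclusion, d))
            if prev is not None:
                assert worlds <= prev
            prev = worlds

    def test_inconsistent_premises_raise(self):
        dnf = alternative_dnf(MEANS, DEFAULT_UNIVERSE, "chance")
        bad = PremisePackage(
            name="refute_everything",
            premises=(Not(dnf),),
            expansion="chance",
        )
        with pytest.raises(InconsistentPremisesError):
            conclude_with_premises(MEANS, None, bad)

    def test_rejecting_the_testable_null_leaves_population_equality_open(self):
        """Eliminating the chance-alone conjunct never refutes population
        equality: its other refinement survives, so the bare equality
        proposition cannot be rejected by the decision rule alone."""
        h0 = testable_null()
        split = Or(
            And(pop_eq(), due_alone(CHANCE)),
            And(pop_eq(), Not(due_alone(CHANCE))),
        )
        d = domain_for(DEFAULT_UNIVERSE, [split])
        assert equivalent(pop_eq(), split, d)
        survivor = And(pop_eq(), Not(due_alone(CHANCE)))
        assert is_satisfiable(And(survivor, Not(h0)), d)
        assert not entails([Not(h0)], Not(pop_eq()), d)
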