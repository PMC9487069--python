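"""Construction and criticism of NHST hypothesis pairs.

The only hypothesis the P-value's conditioning actually addresses is the
conjunction "the population parameters are equal AND the observed sample
difference is due to chance alone" (the *testable null*).  For the pair to
be exhaustive, the alternative must be the negation of that entire
conjunction (the *real alternative*), not the research hypothesis H_T
("the populations differ AND the sample difference is due to that
difference alone"), which is merely one disjunct of the real alternative's
disjunctive normal form.

This module builds those formulas, validates hypothesis pairs (mutual
exclusivity, exhaustiveness, false-dichotomy detection with witness
worlds), locates H_T inside a DNF, and derives conclusions from premise
packages via machine-checked disjunction elimination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .logic_core import (
    And,
    Derivation,
    Domain,
    Formula,
    LogicError,
    Not,
    disjunction_eliminate,
    disjuncts,
    entails,
    equivalent,
    is_satisfiable,
    make_or,
    satisfying_worlds,
)
from .nhst_semantics import (
    BIAS,
    CHANCE,
    DEFAULT_UNIVERSE,
    OPEN_UNIVERSE,
    POPULATION_DIFFERENCE,
    CauseUniverse,
    Scenario,
    WorldState,
    domain_for,
    due_alone,
    due_to,
    not_alone_nor_chance,
    not_involved_nor_chance,
    pop_eq,
    pop_neq,
)

__all__ = [
    "HypothesisPair",
    "PairReport",
    "PremisePackage",
    "ResearchLocation",
    "ConclusionReport",
    "EXPANSION_STYLES",
    "PRESET_PACKAGES",
    "preset_package",
    "testable_null",
    "real_alternative",
    "research_hypothesis",
    "bias_hypothesis",
    "textbook_null",
    "textbook_alternative",
    "expand_alternative",
    "alternative_dnf",
    "canonical_disjunct_sort",
    "locate_research_hypothesis",
    "validate_pair",
    "conclude_with_premises",
]


# ---------------------------------------------------------------------------
# Hypothesis constructors (scenario affects rendering only, never the AST)


def testable_null(s: Scenario | None = None, u: CauseUniverse | None = None) -> Formula:
    """The null hypothesis the P-value can actually test:
    {population parameters equal AND sample difference due to chance alone}."""
    return And(pop_eq(), due_alone(CHANCE))


def real_alternative(h0: Formula) -> Formula:
    """The negation of the *entire* null proposition.

    Negating only part of the null (e.g. keeping just "populations differ")
    produces a non-exhaustive pair; the real alternative is ``NOT(h0)``.
    """
    return Not(h0)


def research_hypothesis() -> Formula:
    """H_T: the populations differ and the sample difference is due to that
    difference alone."""
    return And(pop_neq(), due_alone(POPULATION_DIFFERENCE))


def bias_hypothesis() -> Formula:
    """H_B: the populations are equal and the sample difference is due to
    bias alone."""
    return And(pop_eq(), due_alone(BIAS))


def textbook_null() -> Formula:
    """The bare population-equality proposition often presented as H0."""
    return pop_eq()


def textbook_alternative() -> Formula:
    return pop_neq()


# ---------------------------------------------------------------------------
# DNF expansions of the real alternative

#: Named regroupings of the real alternative into a disjunction.  Each is a
#: list of disjunct-building callables; every expansion is checked
#: equivalent to the real alternative over its domain before use.
EXPANSION_STYLES = ("chance", "research", "bias", "bias_alone")


def _expansion_template(style: str) -> list[Formula]:
    if style == "chance":
        # both population polarities with the chance attribution negated
        return [
            And(pop_eq(), Not(due_alone(CHANCE))),
            And(pop_neq(), Not(due_alone(CHANCE))),
        ]
    if style == "research":
        # refine the unequal-population disjunct to expose H_T
        return [
            And(pop_eq(), Not(due_alone(CHANCE))),
            And(pop_neq(), Not(due_alone(POPULATION_DIFFERENCE))),
            And(pop_neq(), due_alone(POPULATION_DIFFERENCE)),
        ]
    if style == "bias":
        # split the equal-population disjunct on bias involvement
        return [
            And(pop_eq(), not_involved_nor_chance(BIAS)),
            And(pop_eq(), due_to(BIAS)),
            And(pop_neq(), due_alone(POPULATION_DIFFERENCE)),
            And(pop_neq(), Not(due_alone(POPULATION_DIFFERENCE))),
        ]
    if style == "bias_alone":
        # isolate the bias-alone disjunct (used to rig H_B)
        return [
            And(pop_eq(), due_alone(BIAS)),
            And(pop_eq(), not_alone_nor_chance(BIAS)),
            pop_neq(),
        ]
    raise LogicError(f"unknown expansion style {style!r}")


def _is_research_disjunct(f: Formula) -> bool:
    ht_literal = due_alone(POPULATION_DIFFERENCE)
    return any(c == ht_literal for c in (f,)) or (
        isinstance(f, And) and ht_literal in f.children
    )


def canonical_disjunct_sort(parts: list[Formula]) -> list[Formula]:
    """Canonical disjunct order: population-equal disjuncts first, the
    research-hypothesis disjunct last among the rest, otherwise stable."""

    def key(item: tuple[int, Formula]) -> tuple[int, int, int]:
        idx, f = item
        lits = f.children if isinstance(f, And) else (f,)
        eq_first = 0 if pop_eq() in lits else 1
        ht_last = 1 if _is_research_disjunct(f) else 0
        return (eq_first, ht_last, idx)

    return [f for _, f in sorted(enumerate(parts), key=key)]


def expand_alternative(
    u: CauseUniverse,
    style: str = "research",
    *,
    dropped: list[Formula] | None = None,
) -> tuple[Formula, Domain]:
    """The real alternative regrouped as a named disjunction over ``u``.

    Disjuncts that are contradictions over the universe's admissible worlds
    are dropped (and recorded in ``dropped`` when given).  The surviving
    disjunction is verified equivalent to the real alternative before it is
    returned — a failed verification is a bug, not a user error.
    """
    template = _expansion_template(style)
    h0 = testable_null()
    d = domain_for(u, [h0, *template])
    keep: list[Formula] = []
    for dj in template:
        if is_satisfiable(dj, d):
            keep.append(dj)
        elif dropped is not None:
            dropped.append(dj)
    keep = canonical_disjunct_sort(keep) if style != "bias" else keep
    dnf = make_or(keep)
    if not equivalent(dnf, real_alternative(h0), d):
        raise LogicError(
            f"expansion {style!r} is not equivalent to the real alternative "
            f"over universe {u.causes}"
        )
    return dnf, d


def alternative_dnf(
    s: Scenario | None = None,
    u: CauseUniverse = DEFAULT_UNIVERSE,
    style: str = "research",
    *,
    dropped: list[Formula] | None = None,
) -> Formula:
    """DNF of the real alternative with contradictions dropped.

    ``style='chance'`` gives the two-disjunct form (both population
    polarities, chance attribution negated); ``style='research'`` refines
    the unequal-population disjunct so the research hypothesis appears as
    the last disjunct.
    """
    dnf, _ = expand_alternative(u, style, dropped=dropped)
    return dnf


# ---------------------------------------------------------------------------
# Locating the research hypothesis


@dataclass(frozen=True)
class ResearchLocation:
    """Where H_T sits inside a DNF of the alternative."""

    index: int
    disjunct: Formula
    relation: str  # "equal" | "contained"


def locate_research_hypothesis(
    dnf: Formula,
    u: CauseUniverse = DEFAULT_UNIVERSE,
) -> ResearchLocation:
    """Find the disjunct equal to H_T, or the one strictly containing it.

    Matching is semantic over the universe's admissible worlds.  Raises
    :class:`LogicError` when no disjunct even contains H_T (e.g. the DNF of
    the null itself).
    """
    ht = research_hypothesis()
    parts = disjuncts(dnf)
    d = domain_for(u, [dnf, ht])
    for i, dj in enumerate(parts):
        if equivalent(dj, ht, d):
            return ResearchLocation(i, dj, "equal")
    for i, dj in enumerate(parts):
        if entails([ht], dj, d):
            return ResearchLocation(i, dj, "contained")
    raise LogicError("no disjunct matches or contains the research hypothesis")


# ---------------------------------------------------------------------------
# Pair validation


@dataclass
class HypothesisPair:
    """A null/alternative pair under a scenario and a domain.

    No validity is enforced at construction: invalid textbook pairs must be
    representable so they can be criticised by :func:`validate_pair`.
    """

    h0: Formula
    ha: Formula
    scenario: Scenario
    domain: Domain


@dataclass
class PairReport:
    mutually_exclusive: bool
    exhaustive: bool
    verdict: str  # valid | false_dichotomy | overlapping | both_defects
    overlap_witnesses: list[WorldState] = field(default_factory=list)
    gap_witnesses: list[WorldState] = field(default_factory=list)


def validate_pair(p: HypothesisPair) -> PairReport:
    """Check mutual exclusivity and exhaustiveness, with witness worlds.

    A non-exhaustive pair is a *false dichotomy*: some admissible world
    satisfies neither hypothesis, so rejecting one does not license the
    other.  Witnesses are the concrete world states demonstrating each
    defect.
    """
    d = p.domain
    both = satisfying_worlds(And(p.h0, p.ha), d)
    neither = [
        i
        for i in range(len(d.worlds))
        if i not in set(satisfying_worlds(make_or([p.h0, p.ha]), d))
    ]
    exclusive = not both
    exhaustive = not neither
    if exclusive and exhaustive:
        verdict = "valid"
    elif exclusive:
        verdict = "false_dichotomy"
    elif exhaustive:
        verdict = "overlapping"
    else:
        verdict = "both_defects"
    return PairReport(
        mutually_exclusive=exclusive,
        exhaustive=exhaustive,
        verdict=verdict,
        overlap_witnesses=[d.tag_of(i) for i in both],
        gap_witnesses=[d.tag_of(i) for i in neither],
    )


# ---------------------------------------------------------------------------
# Premise packages


@dataclass(frozen=True)
class PremisePackage:
    """A named set of auxiliary premises added to the bare decision rule.

    ``expansion`` names the DNF regrouping of the alternative the premises
    are meant to cut; ``intended_conclusion`` (optional) is compared
    semantically against the derived conclusion.
    """

    name: str
    premises: tuple[Formula, ...]
    intended_conclusion: Formula | None = None
    expansion: str = "research"
    universe: CauseUniverse = DEFAULT_UNIVERSE

    def __post_init__(self) -> None:
        if self.name != "minimum_axiom_set" and not self.premises:
            raise LogicError("a non-minimal premise package needs premises")
        if self.expansion not in EXPANSION_STYLES:
            raise LogicError(f"unknown expansion style {self.expansion!r}")


def _middle_column_conclusion() -> Formula:
    return make_or(
        [
            And(pop_eq(), not_involved_nor_chance(BIAS)),
            And(pop_neq(), Not(due_alone(POPULATION_DIFFERENCE))),
            research_hypothesis(),
        ]
    )


def _build_presets() -> dict[str, PremisePackage]:
    no_chance_combo_eq = Not(And(pop_eq(), Not(due_alone(CHANCE))))
    no_chance_combo_neq = Not(
        And(pop_neq(), not_alone_nor_chance(POPULATION_DIFFERENCE))
    )
    return {
        "minimum_axiom_set": PremisePackage(
            name="minimum_axiom_set",
            premises=(),
            intended_conclusion=None,
            expansion="research",
        ),
        # aim to conclude H_T: rule out the equal-population combination
        # hypotheses and the unequal-population combinations in which the
        # sample difference is not due to the population difference alone
        "table3_conclude_HT": PremisePackage(
            name="table3_conclude_HT",
            premises=(no_chance_combo_eq, no_chance_combo_neq),
            intended_conclusion=research_hypothesis(),
            expansion="research",
        ),
        # assume only "there is no bias": the conclusion stays a
        # three-way disjunction strictly wider than H_T
        "table3_no_bias_only": PremisePackage(
            name="table3_no_bias_only",
            premises=(Not(And(pop_eq(), due_to(BIAS))),),
            intended_conclusion=_middle_column_conclusion(),
            expansion="bias",
            universe=OPEN_UNIVERSE,
        ),
        # a different premise package rigs the bias hypothesis instead
        "table3_conclude_HB": PremisePackage(
            name="table3_conclude_HB",
            premises=(
                Not(And(pop_eq(), not_alone_nor_chance(BIAS))),
                pop_eq(),
            ),
            intended_conclusion=bias_hypothesis(),
            expansion="bias_alone",
        ),
    }


PRESET_PACKAGES: dict[str, PremisePackage] = _build_presets()


def preset_package(name: str) -> PremisePackage:
    try:
        return PRESET_PACKAGES[name]
    except KeyError:
        raise LogicError(
            f"unknown preset {name!r}; available: {sorted(PRESET_PACKAGES)}"
        ) from None


# ---------------------------------------------------------------------------
# Deriving conclusions


@dataclass
class ConclusionReport:
    conclusion: Formula
    derivation: Derivation
    package: PremisePackage
    universe: CauseUniverse
    dnf: Formula
    reached_intended: bool | None  # None when no intended conclusion given


def conclude_with_premises(
    s: Scenario | None,
    u: CauseUniverse | None,
    pkg: PremisePackage,
) -> ConclusionReport:
    """Apply a premise package to the real alternative's DNF.

    Runs disjunction elimination over the package's expansion of the
    alternative; the returned derivation is machine-checkable against the
    domain.  Surviving disjuncts are reported in canonical order (research
    hypothesis last).  Raises
    :class:`~nhst_logic.logic_core.InconsistentPremisesError` when the
    premises refute every disjunct.
    """
    universe = u or pkg.universe
    dnf, domain = expand_alternative(universe, pkg.expansion)
    # premises may mention atoms the expansion does not
    domain = domain_for(universe, [dnf, *pkg.premises])
    conclusion, deriv = disjunction_eliminate(dnf, pkg.premises, domain)
    conclusion = make_or(canonical_disjunct_sort(list(disjuncts(conclusion))))
    reached: bool | None = None
    if pkg.intended_conclusion is not None:
        check_domain = domain_for(
            universe, [conclusion, pkg.intended_conclusion]
        )
        reached = equivalent(conclusion, pkg.intended_conclusion, check_domain)
    return ConclusionReport(
        conclusion=conclusion,
        derivation=deriv,
        package=pkg,
        universe=universe,
        dnf=dnf,
        reached_intended=reached,
    )
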