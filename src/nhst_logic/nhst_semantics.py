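"""Finite world-state semantics for hypotheses about group differences.

An admissible *world state* pairs a population relation (the population
parameters are equal or not) with the non-empty set of causes that produced
the observed difference between the sample groups.  Two structural
constraints define admissibility:

* the population difference is an active cause if and only if the
  populations actually differ (this single invariant is what makes
  "(mu1 != mu2) AND [sample difference due to chance alone]" a
  contradiction rather than an extra axiom), and
* the set of active causes is never empty — exact equality of two sample
  means from continuous data is a probability-zero event, so an observed
  difference always exists and something produced it.

Atoms over these worlds are causal-attribution propositions ("the sample
difference is due to chance alone", "... not due to bias nor chance
alone", ...) plus the population-equality proposition.  A
:class:`Scenario` binds the abstract atoms to a rendering vocabulary
(means, proportions, correlation, or plain prose) and never affects the
semantics.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Iterator, Sequence

from .logic_core import (
    FALSE,
    And,
    Atom,
    Const,
    Domain,
    Formula,
    LogicError,
    Not,
    Or,
    Var,
    make_and,
    make_or,
    substitute,
)

__all__ = [
    "CHANCE",
    "POPULATION_DIFFERENCE",
    "BIAS",
    "OTHER",
    "CauseUniverse",
    "WorldState",
    "AtomSpec",
    "Scenario",
    "ConfigurationError",
    "EmptyFormulaError",
    "TWO_CAUSE_UNIVERSE",
    "DEFAULT_UNIVERSE",
    "OPEN_UNIVERSE",
    "SCENARIOS",
    "MEANS",
    "PROPORTIONS",
    "CORRELATION",
    "GENERIC",
    "POP_EQ_ID",
    "SAMPLE_EQ_ID",
    "pop_eq",
    "pop_neq",
    "sample_eq",
    "due_alone",
    "not_due_alone",
    "due_to",
    "due_to_exactly",
    "not_alone_nor_chance",
    "not_involved_nor_chance",
    "spec_from_id",
    "atom_truth",
    "enumerate_worlds",
    "domain_for",
    "worlds_to_csv",
    "simplify_sample_equality",
    "render",
    "parse",
    "to_ascii",
]

CHANCE = "chance"
POPULATION_DIFFERENCE = "population_difference"
BIAS = "bias"
OTHER = "other"

POP_EQ_ID = "pop_eq"
SAMPLE_EQ_ID = "sample_eq"


class ConfigurationError(LogicError):
    """An invalid cause universe or scenario configuration."""


class EmptyFormulaError(LogicError):
    """Simplification removed the entire formula (it consisted only of
    probability-zero content)."""


# ---------------------------------------------------------------------------
# Cause universes and world states


@dataclass(frozen=True)
class CauseUniverse:
    """The closed set of candidate causes of the observed sample difference.

    Must contain ``population_difference`` (the intervention / true effect)
    and at least one other cause; ``chance`` is required so that sampling
    noise is always representable.
    """

    causes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.causes)) != len(self.causes):
            raise ConfigurationError("cause labels must be unique")
        if len(self.causes) < 2:
            raise ConfigurationError("a cause universe needs at least two causes")
        if POPULATION_DIFFERENCE not in self.causes:
            raise ConfigurationError(
                f"cause universe must contain {POPULATION_DIFFERENCE!r}"
            )
        if CHANCE not in self.causes:
            raise ConfigurationError(f"cause universe must contain {CHANCE!r}")

    @property
    def non_population(self) -> tuple[str, ...]:
        return tuple(c for c in self.causes if c != POPULATION_DIFFERENCE)

    def __contains__(self, cause: str) -> bool:
        return cause in self.causes


#: chance vs the true effect only — the idealised two-alternative model
TWO_CAUSE_UNIVERSE = CauseUniverse((CHANCE, POPULATION_DIFFERENCE))
#: chance, bias or the intervention (or combinations) — the default model
DEFAULT_UNIVERSE = CauseUniverse((CHANCE, BIAS, POPULATION_DIFFERENCE))
#: open model admitting an unspecified further cause
OPEN_UNIVERSE = CauseUniverse((CHANCE, BIAS, OTHER, POPULATION_DIFFERENCE))


@dataclass(frozen=True)
class WorldState:
    """One admissible state of affairs."""

    population_equal: bool
    active_causes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "active_causes", frozenset(self.active_causes))
        if not self.active_causes:
            raise ConfigurationError(
                "active_causes must be non-empty (the sample difference "
                "is always observed)"
            )
        if self.population_equal == (POPULATION_DIFFERENCE in self.active_causes):
            raise ConfigurationError(
                "population_equal must hold exactly when the population "
                "difference is not an active cause"
            )

    def describe(self, scenario: "Scenario | None" = None) -> str:
        s = scenario or MEANS
        rel = s.eq_str if self.population_equal else s.neq_str
        causes = ", ".join(sorted(self.active_causes))
        return f"{rel} with sample difference produced by {{{causes}}}"


def enumerate_worlds(u: CauseUniverse) -> list[WorldState]:
    """All admissible world states of a universe, in deterministic order.

    Population-equal worlds come first (active causes are the non-empty
    subsets of the non-population causes), then population-unequal worlds
    (subsets containing the population difference), each block ordered by
    subset size then by cause order.  A universe with k causes yields
    (2^(k-1) - 1) + 2^(k-1) worlds.
    """
    others = u.non_population
    worlds: list[WorldState] = []
    for size in range(1, len(others) + 1):
        for combo in combinations(others, size):
            worlds.append(WorldState(True, frozenset(combo)))
    for size in range(0, len(others) + 1):
        for combo in combinations(others, size):
            worlds.append(
                WorldState(False, frozenset((POPULATION_DIFFERENCE, *combo)))
            )
    return worlds


# ---------------------------------------------------------------------------
# Atom specifications


_MODES = {
    "due_to_alone",
    "due_to",
    "due_to_exactly",
    "not_due_to_alone_nor_chance_alone",
    "not_due_to_nor_chance_alone",
}


@dataclass(frozen=True)
class AtomSpec:
    """Interpretation of one atom over world states.

    kinds: ``population_equal``, ``sample_equal`` (the reserved
    probability-zero proposition that the sample statistics are exactly
    equal) and ``attribution`` with one of the modes:

    ``due_to_alone(c)``
        c is the only active cause.
    ``due_to(c)``
        c is among the active causes (possibly in combination).
    ``due_to_exactly(S)``
        the active causes are exactly the set S.
    ``not_due_to_alone_nor_chance_alone(c)``
        the active causes are neither {c} nor {chance}.
    ``not_due_to_nor_chance_alone(c)``
        c is not active at all, and the active causes are not {chance}.
    """

    kind: str
    mode: str = ""
    causes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in {"population_equal", "sample_equal", "attribution"}:
            raise ConfigurationError(f"unknown atom kind {self.kind!r}")
        if self.kind == "attribution":
            if self.mode not in _MODES:
                raise ConfigurationError(f"unknown attribution mode {self.mode!r}")
            if not self.causes:
                raise ConfigurationError("attribution atom needs cause arguments")

    @property
    def id(self) -> str:
        if self.kind == "population_equal":
            return POP_EQ_ID
        if self.kind == "sample_equal":
            return SAMPLE_EQ_ID
        if self.mode == "due_to_alone":
            return f"alone:{self.causes[0]}"
        if self.mode == "due_to":
            return f"involves:{self.causes[0]}"
        if self.mode == "due_to_exactly":
            return "exactly:" + "+".join(sorted(self.causes))
        if self.mode == "not_due_to_alone_nor_chance_alone":
            return f"not_alone_nor_chance:{self.causes[0]}"
        return f"not_involved_nor_chance:{self.causes[0]}"


def spec_from_id(atom_id: str) -> AtomSpec:
    """Invert :attr:`AtomSpec.id` (ids are structured strings)."""
    if atom_id == POP_EQ_ID:
        return AtomSpec("population_equal")
    if atom_id == SAMPLE_EQ_ID:
        return AtomSpec("sample_equal")
    prefix, _, arg = atom_id.partition(":")
    table = {
        "alone": "due_to_alone",
        "involves": "due_to",
        "exactly": "due_to_exactly",
        "not_alone_nor_chance": "not_due_to_alone_nor_chance_alone",
        "not_involved_nor_chance": "not_due_to_nor_chance_alone",
    }
    if prefix not in table or not arg:
        raise ConfigurationError(f"unparseable atom id {atom_id!r}")
    causes = tuple(arg.split("+")) if prefix == "exactly" else (arg,)
    return AtomSpec("attribution", table[prefix], causes)


def atom_truth(a: AtomSpec, w: WorldState) -> bool:
    """Truth of an atom in a world state."""
    if a.kind == "population_equal":
        return w.population_equal
    if a.kind == "sample_equal":
        return False  # probability-zero event: false in every admissible world
    active = w.active_causes
    if a.mode == "due_to_alone":
        return active == {a.causes[0]}
    if a.mode == "due_to":
        return a.causes[0] in active
    if a.mode == "due_to_exactly":
        return active == set(a.causes)
    if a.mode == "not_due_to_alone_nor_chance_alone":
        return active != {a.causes[0]} and active != {CHANCE}
    if a.mode == "not_due_to_nor_chance_alone":
        return a.causes[0] not in active and active != {CHANCE}
    raise ConfigurationError(f"unknown attribution mode {a.mode!r}")


# --- formula helpers -------------------------------------------------------


def pop_eq() -> Formula:
    """The population parameters are equal (no true finding)."""
    return Var(POP_EQ_ID)


def pop_neq() -> Formula:
    return Not(pop_eq())


def sample_eq() -> Formula:
    """The reserved probability-zero sample-equality proposition."""
    return Var(SAMPLE_EQ_ID)


def due_alone(cause: str) -> Formula:
    return Var(AtomSpec("attribution", "due_to_alone", (cause,)).id)


def not_due_alone(cause: str) -> Formula:
    return Not(due_alone(cause))


def due_to(cause: str) -> Formula:
    return Var(AtomSpec("attribution", "due_to", (cause,)).id)


def due_to_exactly(*causes: str) -> Formula:
    return Var(AtomSpec("attribution", "due_to_exactly", tuple(causes)).id)


def not_alone_nor_chance(cause: str) -> Formula:
    return Var(
        AtomSpec("attribution", "not_due_to_alone_nor_chance_alone", (cause,)).id
    )


def not_involved_nor_chance(cause: str) -> Formula:
    return Var(AtomSpec("attribution", "not_due_to_nor_chance_alone", (cause,)).id)


# ---------------------------------------------------------------------------
# Domain construction


def _iter_atom_ids(f: Formula) -> Iterator[str]:
    if isinstance(f, Var):
        yield f.atom
    elif isinstance(f, Not):
        yield from _iter_atom_ids(f.child)
    elif isinstance(f, (And, Or)):
        for c in f.children:
            yield from _iter_atom_ids(c)


def _check_causes(spec: AtomSpec, u: CauseUniverse) -> None:
    for c in spec.causes:
        if c not in u:
            raise ConfigurationError(
                f"unknown cause label {c!r} for universe {u.causes}"
            )


def domain_for(
    u: CauseUniverse,
    formulas: Iterable[Formula] = (),
    extra_specs: Iterable[AtomSpec] = (),
) -> Domain:
    """Build the admissible-world :class:`Domain` for a cause universe.

    The atom vocabulary is the population-equality atom, the sample-equality
    atom, the due-to-alone atom of every cause, plus every further atom
    mentioned by the given formulas.  Worlds carry their generating
    :class:`WorldState` as the tag, so equivalence failures can report
    concrete witness states.
    """
    seen: dict[str, AtomSpec] = {}

    def add(spec: AtomSpec) -> None:
        _check_causes(spec, u)
        seen.setdefault(spec.id, spec)

    add(AtomSpec("population_equal"))
    add(AtomSpec("sample_equal"))
    for c in u.causes:
        add(AtomSpec("attribution", "due_to_alone", (c,)))
    for f in formulas:
        for atom_id in _iter_atom_ids(f):
            if atom_id not in seen:
                add(spec_from_id(atom_id))
    for spec in extra_specs:
        add(spec)

    states = enumerate_worlds(u)
    atoms = tuple(Atom(i, i) for i in seen)
    worlds = tuple(
        {i: atom_truth(spec, w) for i, spec in seen.items()} for w in states
    )
    return Domain(atoms=atoms, worlds=worlds, tags=tuple(states))


def worlds_to_csv(u: CauseUniverse) -> str:
    """Export the world enumeration as CSV (one row per admissible world)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["population_equal", "active_causes"])
    for w in enumerate_worlds(u):
        writer.writerow(
            ["T" if w.population_equal else "F", "+".join(sorted(w.active_causes))]
        )
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Probability-zero simplification


def simplify_sample_equality(f: Formula) -> Formula:
    """Eliminate the sample-equality proposition from a formula.

    Exact equality of the sample statistics has probability zero under
    continuous sampling, so the reserved atom is false in every admissible
    world; any disjunct that asserts it drops out and any conjunct
    containing it falsifies its conjunction.  The result is equivalent to
    the input over every admissible domain.  A formula consisting only of
    sample-equality content collapses to nothing and raises
    :class:`EmptyFormulaError`.
    """
    out = substitute(f, {SAMPLE_EQ_ID: False})
    if out == FALSE:
        raise EmptyFormulaError(
            "formula consists only of sample-equality content"
        )
    return out


# ---------------------------------------------------------------------------
# Scenarios and rendering


@dataclass(frozen=True)
class Scenario:
    """Vocabulary binding for rendering formulas; never affects semantics.

    ``population_pair`` fills the equality/inequality slot and
    ``sample_pair`` the attribution slot.  ``stat_family`` names the test
    statistic conventionally used for the scenario.
    """

    name: str
    population_pair: tuple[str, str]
    sample_pair: tuple[str, str]
    stat_family: str = ""
    wrap_sample: bool = True   # parenthesise the sample-difference phrase
    brace_conj: bool = True    # brace a top-level conjunction
    conj_brackets: tuple[str, str] = ("{", "}")
    attr_brackets: tuple[str, str] = ("[", "]")
    prose: bool = False

    def __post_init__(self) -> None:
        if not (self.population_pair[0] and self.sample_pair[0]):
            raise ConfigurationError("scenario symbols must be non-empty")

    @property
    def eq_str(self) -> str:
        if self.prose:
            return "there is no finding in the population"
        a, b = self.population_pair
        return f"({a} = {b})"

    @property
    def neq_str(self) -> str:
        if self.prose:
            return "there is a finding in the population"
        a, b = self.population_pair
        return f"({a} ≠ {b})"

    @property
    def sdiff_str(self) -> str:
        a, b = self.sample_pair
        s = f"{a} ≠ {b}"
        return f"({s})" if self.wrap_sample else s

    @property
    def seq_str(self) -> str:
        a, b = self.sample_pair
        s = f"{a} = {b}"
        return f"({s})" if self.wrap_sample else s


MEANS = Scenario("means", ("μ1", "μ2"), ("x̄1", "x̄2"), "t")
PROPORTIONS = Scenario(
    "proportions", ("p̂1", "p̂2"), ("p1", "p2"), "chi2"
)
CORRELATION = Scenario(
    "correlation",
    ("ρ", "0"),
    ("r", "0"),
    "corr_t",
    wrap_sample=False,
    brace_conj=False,
    conj_brackets=("(", ")"),
    attr_brackets=("(", ")"),
)
GENERIC = Scenario(
    "generic",
    ("population finding", "none"),
    ("sample finding", "none"),
    "",
    prose=True,
)

SCENARIOS: dict[str, Scenario] = {
    s.name: s for s in (MEANS, PROPORTIONS, CORRELATION, GENERIC)
}


def _cause_phrase(cause: str, s: Scenario) -> str:
    if cause == POPULATION_DIFFERENCE:
        return "the population finding" if s.prose else s.neq_str
    return cause


def _attr_body(spec: AtomSpec, s: Scenario, negated: bool) -> str:
    subject = (
        "the finding in the sample group" if s.prose else s.sdiff_str
    )
    m, cs = spec.mode, spec.causes
    if m == "due_to_alone":
        phrase = f"due to {_cause_phrase(cs[0], s)} alone"
        if negated:
            phrase = "not " + phrase
    elif m == "due_to":
        phrase = f"due to {_cause_phrase(cs[0], s)}"
        if negated:
            phrase = "not " + phrase
    elif m == "due_to_exactly":
        listing = " and ".join(_cause_phrase(c, s) for c in cs)
        phrase = f"due to {listing}"
        if negated:
            phrase = "not " + phrase
    elif m == "not_due_to_alone_nor_chance_alone":
        core = f"due to {_cause_phrase(cs[0], s)} alone nor chance alone"
        phrase = core if negated else "not " + core
    else:  # not_due_to_nor_chance_alone
        core = f"due to {_cause_phrase(cs[0], s)} nor chance alone"
        phrase = core if negated else "not " + core
    return f"{subject} is {phrase}" if s.prose else f"{subject} {phrase}"


def _render_literal(atom_id: str, s: Scenario, negated: bool) -> str:
    spec = spec_from_id(atom_id)
    if spec.kind == "population_equal":
        return s.neq_str if negated else s.eq_str
    if spec.kind == "sample_equal":
        if negated:
            return s.sdiff_str
        if s.prose:
            return "there is no finding in the sample group"
        return s.seq_str
    body = _attr_body(spec, s, negated)
    if s.prose:
        return body
    lo, hi = s.attr_brackets
    return f"{lo}{body}{hi}"


def render(f: Formula, s: Scenario, *, top: bool = True) -> str:
    """Deterministic text for a formula in a scenario's vocabulary.

    Unicode symbols by default; pass the result through :func:`to_ascii`
    for a plain-ASCII rendering.
    """
    if isinstance(f, Const):
        return "⊤" if f.value else "⊥"
    if isinstance(f, Var):
        return _render_literal(f.atom, s, negated=False)
    if isinstance(f, Not):
        if isinstance(f.child, Var):
            return _render_literal(f.child.atom, s, negated=True)
        if s.prose:
            return f"it is not the case that ({render(f.child, s, top=True)})"
        return f"¬{render(f.child, s, top=False)}"
    if isinstance(f, And):
        sep = " and " if s.prose else " ∧ "
        body = sep.join(render(c, s, top=False) for c in f.children)
        if s.prose:
            return body if top else f"({body})"
        if s.brace_conj or not top:
            lo, hi = s.conj_brackets
            return f"{lo}{body}{hi}"
        return body
    if isinstance(f, Or):
        sep = " or " if s.prose else " ∨ "
        body = sep.join(render(c, s, top=False) for c in f.children)
        return body if top else f"({body})"
    raise LogicError(f"unknown formula node {f!r}")


_ASCII_MAP = [
    ("μ", "mu"),
    ("x̄", "xbar"),
    ("p̂", "phat"),
    ("ρ", "rho"),
    ("≠", "!="),
    ("∧", "and"),
    ("∨", "or"),
    ("¬", "not "),
    ("⊤", "true"),
    ("⊥", "false"),
]


def to_ascii(text: str) -> str:
    """Portable ASCII fallback for a rendered formula (mu1 != mu2 etc.)."""
    for uni, plain in _ASCII_MAP:
        text = text.replace(uni, plain)
    return text


# ---------------------------------------------------------------------------
# Parsing rendered text back to formulas


def _candidate_literals(
    s: Scenario, u: CauseUniverse
) -> list[tuple[str, Formula]]:
    lits: list[tuple[str, Formula]] = []

    def add(formula: Formula) -> None:
        lits.append((render(formula, s, top=False), formula))
        if isinstance(formula, Var):
            lits.append((render(Not(formula), s, top=False), Not(formula)))

    add(pop_eq())
    add(sample_eq())
    for c in u.causes:
        add(due_alone(c))
        add(due_to(c))
        add(not_alone_nor_chance(c))
        add(not_involved_nor_chance(c))
    causes = list(u.causes)
    for size in range(1, len(causes) + 1):
        for combo in combinations(causes, size):
            add(due_to_exactly(*combo))
    lits.sort(key=lambda kv: -len(kv[0]))
    return lits


_OPEN = "([{"
_CLOSE = ")]}"


def _tokenize(
    text: str, literals: Sequence[tuple[str, Formula]]
) -> list[tuple[str, Formula | None]]:
    tokens: list[tuple[str, Formula | None]] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        matched = False
        for phrase, formula in literals:
            if text.startswith(phrase, i):
                tokens.append(("atom", formula))
                i += len(phrase)
                matched = True
                break
        if matched:
            continue
        if ch == "¬":
            tokens.append(("not", None))
        elif ch == "∧":
            tokens.append(("and", None))
        elif ch == "∨":
            tokens.append(("or", None))
        elif ch in _OPEN:
            tokens.append(("open", None))
        elif ch in _CLOSE:
            tokens.append(("close", None))
        else:
            raise LogicError(f"cannot tokenize at ...{text[i:i + 30]!r}")
        i += 1
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, Formula | None]]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def expr(self) -> Formula:
        parts = [self.conj()]
        while self.peek() == "or":
            self.pos += 1
            parts.append(self.conj())
        return make_or(parts)

    def conj(self) -> Formula:
        parts = [self.unary()]
        while self.peek() == "and":
            self.pos += 1
            parts.append(self.unary())
        return make_and(parts)

    def unary(self) -> Formula:
        kind = self.peek()
        if kind == "not":
            self.pos += 1
            return Not(self.unary())
        if kind == "open":
            self.pos += 1
            inner = self.expr()
            if self.peek() != "close":
                raise LogicError("unbalanced brackets in rendered formula")
            self.pos += 1
            return inner
        if kind == "atom":
            f = self.tokens[self.pos][1]
            self.pos += 1
            assert f is not None
            return f
        raise LogicError(f"unexpected token {kind!r}")


def parse(text: str, s: Scenario, u: CauseUniverse = DEFAULT_UNIVERSE) -> Formula:
    """Parse a symbolically rendered formula back to its AST.

    Supports the symbolic scenarios (means, proportions, correlation); the
    prose rendering of the generic scenario is write-only.  Round-trips of
    :func:`render` are semantically equivalent to the original formula.
    """
    if s.prose:
        raise ConfigurationError("the generic prose rendering cannot be parsed")
    parser = _Parser(_tokenize(text, _candidate_literals(s, u)))
    out = parser.expr()
    if parser.pos != len(parser.tokens):
        raise LogicError("trailing tokens after formula")
    return out
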