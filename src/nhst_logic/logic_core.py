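"""Propositional calculus over finite admissible-world domains.

This is the engine underneath the hypothesis framework: formulas are finite
trees of atoms, negations, conjunctions and disjunctions; semantics are
always relative to a :class:`Domain`, a finite set of admissible total truth
assignments.  Working relative to a domain (rather than the free Boolean
algebra) is the point: the equivalences between null/alternative hypothesis
forms hold only under the sample-space constraints that the domain encodes.
A free domain over named atoms is available for ordinary truth-table work.

Everything is decided by exhaustive enumeration — domains here have at most
a few dozen worlds, so no SAT machinery is needed or wanted.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from itertools import product
from typing import Any, Callable, Iterable, Mapping, Sequence

__all__ = [
    "Atom",
    "Formula",
    "Var",
    "Not",
    "And",
    "Or",
    "Const",
    "TRUE",
    "FALSE",
    "Domain",
    "TruthTable",
    "Derivation",
    "DerivationStep",
    "LogicError",
    "EvaluationError",
    "InconsistentPremisesError",
    "free_domain",
    "evaluate",
    "satisfying_worlds",
    "is_satisfiable",
    "is_contradiction",
    "is_tautology",
    "equivalent",
    "entails",
    "truth_table",
    "to_dnf",
    "disjuncts",
    "conjuncts",
    "make_or",
    "make_and",
    "substitute",
    "disjunction_eliminate",
    "formula_to_json",
    "formula_from_json",
]


class LogicError(ValueError):
    """Base class for errors raised by the logic engine."""


class EvaluationError(LogicError):
    """A formula references an atom the world does not assign."""


class InconsistentPremisesError(LogicError):
    """Disjunction elimination removed every disjunct: the premise set is
    inconsistent with the disjunction."""


@dataclass(frozen=True)
class Atom:
    """A named propositional atom.

    ``id`` is the opaque identifier used in formulas and worlds; ``label``
    is free human-readable text (defaults to the id).
    """

    id: str
    label: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise LogicError("atom id must be non-empty")
        if not self.label:
            object.__setattr__(self, "label", self.id)


# ---------------------------------------------------------------------------
# Formulas


class Formula:
    """Base class for propositional formulas.

    Subclasses: :class:`Var` (atom reference), :class:`Not`, :class:`And`,
    :class:`Or`, :class:`Const`.  Instances are immutable and hashable;
    ``&``, ``|`` and ``~`` build larger formulas.
    """

    def atoms(self) -> frozenset[str]:
        raise NotImplementedError

    def __and__(self, other: "Formula") -> "Formula":
        return make_and([self, other])

    def __or__(self, other: "Formula") -> "Formula":
        return make_or([self, other])

    def __invert__(self) -> "Formula":
        return Not(self)


@dataclass(frozen=True)
class Var(Formula):
    atom: str

    def atoms(self) -> frozenset[str]:
        return frozenset({self.atom})

    def __repr__(self) -> str:
        return self.atom


@dataclass(frozen=True)
class Not(Formula):
    child: Formula

    def atoms(self) -> frozenset[str]:
        return self.child.atoms()

    def __repr__(self) -> str:
        return f"~{self.child!r}"


def _flatten(cls: type, children: Iterable[Formula]) -> tuple[Formula, ...]:
    out: list[Formula] = []
    for c in children:
        if isinstance(c, cls):
            out.extend(c.children)  # type: ignore[attr-defined]
        else:
            out.append(c)
    return tuple(out)


@dataclass(frozen=True)
class And(Formula):
    children: tuple[Formula, ...]

    def __init__(self, *children: Formula | Iterable[Formula]):
        flat = _coerce_children(children)
        if len(flat) < 2:
            raise LogicError("And requires at least two children")
        object.__setattr__(self, "children", _flatten(And, flat))

    def atoms(self) -> frozenset[str]:
        return frozenset().union(*(c.atoms() for c in self.children))

    def __repr__(self) -> str:
        return "(" + " & ".join(map(repr, self.children)) + ")"


@dataclass(frozen=True)
class Or(Formula):
    children: tuple[Formula, ...]

    def __init__(self, *children: Formula | Iterable[Formula]):
        flat = _coerce_children(children)
        if len(flat) < 2:
            raise LogicError("Or requires at least two children")
        object.__setattr__(self, "children", _flatten(Or, flat))

    def atoms(self) -> frozenset[str]:
        return frozenset().union(*(c.atoms() for c in self.children))

    def __repr__(self) -> str:
        return "(" + " | ".join(map(repr, self.children)) + ")"


@dataclass(frozen=True)
class Const(Formula):
    """Propositional constant (verum / falsum)."""

    value: bool

    def atoms(self) -> frozenset[str]:
        return frozenset()

    def __repr__(self) -> str:
        return "TRUE" if self.value else "FALSE"


TRUE = Const(True)
FALSE = Const(False)


def _coerce_children(children: tuple) -> list[Formula]:
    flat: list[Formula] = []
    for c in children:
        if isinstance(c, Formula):
            flat.append(c)
        else:
            flat.extend(c)
    return flat


def make_and(children: Sequence[Formula]) -> Formula:
    """N-ary conjunction that unwraps the single-child case."""
    if len(children) == 0:
        return TRUE
    if len(children) == 1:
        return children[0]
    return And(*children)


def make_or(children: Sequence[Formula]) -> Formula:
    """N-ary disjunction that unwraps the single-child case."""
    if len(children) == 0:
        return FALSE
    if len(children) == 1:
        return children[0]
    return Or(*children)


def disjuncts(f: Formula) -> tuple[Formula, ...]:
    """The top-level disjuncts of ``f`` (``f`` itself if not a disjunction)."""
    return f.children if isinstance(f, Or) else (f,)


def conjuncts(f: Formula) -> tuple[Formula, ...]:
    return f.children if isinstance(f, And) else (f,)


# ---------------------------------------------------------------------------
# Domains


@dataclass(frozen=True)
class Domain:
    """A finite set of admissible worlds over a fixed atom vocabulary.

    ``worlds`` are total truth assignments (atom id -> bool); ``tags`` is an
    optional parallel sequence of per-world metadata (e.g. the world state a
    row was generated from), used for witness reporting.
    """

    atoms: tuple[Atom, ...]
    worlds: tuple[Mapping[str, bool], ...]
    tags: tuple[Any, ...] = ()

    def __post_init__(self) -> None:
        ids = [a.id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise LogicError("duplicate atom ids in domain")
        if not self.worlds:
            raise LogicError("domain must contain at least one world")
        for w in self.worlds:
            missing = set(ids) - set(w)
            if missing:
                raise LogicError(f"world {w} misses atoms {sorted(missing)}")
        if self.tags and len(self.tags) != len(self.worlds):
            raise LogicError("tags must parallel worlds")

    @property
    def atom_ids(self) -> tuple[str, ...]:
        return tuple(a.id for a in self.atoms)

    def check_formula(self, f: Formula) -> None:
        extra = f.atoms() - set(self.atom_ids)
        if extra:
            raise EvaluationError(
                f"formula uses atoms not in domain: {sorted(extra)}"
            )

    def tag_of(self, index: int) -> Any:
        return self.tags[index] if self.tags else index


def free_domain(atom_ids: Sequence[str]) -> Domain:
    """The free Boolean domain: all 2^k assignments over the given atoms.

    This is the semantics of an ordinary textbook truth table, with rows in
    the conventional order (first atom varies slowest, T before F).
    """
    if not atom_ids:
        raise LogicError("free domain needs at least one atom")
    atoms = tuple(Atom(a) for a in atom_ids)
    worlds = tuple(
        dict(zip(atom_ids, values))
        for values in product((True, False), repeat=len(atom_ids))
    )
    return Domain(atoms=atoms, worlds=worlds)


# ---------------------------------------------------------------------------
# Semantics


def evaluate(f: Formula, w: Mapping[str, bool]) -> bool:
    """Truth value of ``f`` in world ``w`` under standard semantics."""
    if isinstance(f, Const):
        return f.value
    if isinstance(f, Var):
        try:
            return bool(w[f.atom])
        except KeyError:
            raise EvaluationError(f"atom {f.atom!r} not assigned in world") from None
    if isinstance(f, Not):
        return not evaluate(f.child, w)
    if isinstance(f, And):
        return all(evaluate(c, w) for c in f.children)
    if isinstance(f, Or):
        return any(evaluate(c, w) for c in f.children)
    raise LogicError(f"unknown formula node {f!r}")


def satisfying_worlds(f: Formula, d: Domain) -> list[int]:
    """Indices of the admissible worlds of ``d`` in which ``f`` holds."""
    d.check_formula(f)
    return [i for i, w in enumerate(d.worlds) if evaluate(f, w)]


def is_satisfiable(f: Formula, d: Domain) -> bool:
    return bool(satisfying_worlds(f, d))


def is_contradiction(f: Formula, d: Domain) -> bool:
    """True iff ``f`` is false in every admissible world of ``d``."""
    return not is_satisfiable(f, d)


def is_tautology(f: Formula, d: Domain) -> bool:
    """True iff ``f`` is true in every admissible world of ``d``."""
    return is_contradiction(Not(f), d)


def equivalent(f: Formula, g: Formula, d: Domain) -> bool:
    """Domain equivalence: ``f`` and ``g`` agree on every admissible world."""
    d.check_formula(f)
    d.check_formula(g)
    return all(evaluate(f, w) == evaluate(g, w) for w in d.worlds)


def entails(premises: Iterable[Formula], conclusion: Formula, d: Domain) -> bool:
    """Every admissible world satisfying all premises satisfies the conclusion."""
    premises = list(premises)
    for f in premises:
        d.check_formula(f)
    d.check_formula(conclusion)
    for w in d.worlds:
        if all(evaluate(p, w) for p in premises) and not evaluate(conclusion, w):
            return False
    return True


# ---------------------------------------------------------------------------
# Truth tables


@dataclass(frozen=True)
class TruthTable:
    """One row per admissible world, one column per formula."""

    columns: tuple[Formula, ...]
    atom_ids: tuple[str, ...]
    rows: tuple[tuple[bool, ...], ...]          # formula values per world
    assignments: tuple[tuple[bool, ...], ...]   # atom values per world
    headers: tuple[str, ...] = ()

    def column(self, j: int) -> tuple[bool, ...]:
        return tuple(row[j] for row in self.rows)

    def _header_row(self) -> list[str]:
        heads = list(self.headers) if self.headers else [repr(c) for c in self.columns]
        return list(self.atom_ids) + heads

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(self._header_row())
        for assign, row in zip(self.assignments, self.rows):
            writer.writerow(["T" if v else "F" for v in (*assign, *row)])
        return buf.getvalue()

    def to_text(self) -> str:
        """Aligned plain-text rendering in the style of a textbook table."""
        header = self._header_row()
        body = [
            ["T" if v else "F" for v in (*assign, *row)]
            for assign, row in zip(self.assignments, self.rows)
        ]
        widths = [
            max(len(header[j]), *(len(r[j]) for r in body)) for j in range(len(header))
        ]
        lines = [
            "  ".join(h.ljust(w) for h, w in zip(header, widths)),
            "  ".join("-" * w for w in widths),
        ]
        for r in body:
            lines.append("  ".join(v.center(w) for v, w in zip(r, widths)))
        return "\n".join(lines)


def truth_table(
    fs: Sequence[Formula],
    d: Domain,
    headers: Sequence[str] | None = None,
) -> TruthTable:
    """Evaluate each formula in every admissible world of the domain."""
    if not fs:
        raise LogicError("truth_table requires at least one formula")
    for f in fs:
        d.check_formula(f)
    rows = tuple(tuple(evaluate(f, w) for f in fs) for w in d.worlds)
    assignments = tuple(
        tuple(bool(w[a]) for a in d.atom_ids) for w in d.worlds
    )
    return TruthTable(
        columns=tuple(fs),
        atom_ids=d.atom_ids,
        rows=rows,
        assignments=assignments,
        headers=tuple(headers) if headers is not None else (),
    )


# ---------------------------------------------------------------------------
# Disjunctive normal form


def to_dnf(
    f: Formula,
    d: Domain,
    *,
    dropped: list[Formula] | None = None,
) -> Formula:
    """Canonical DNF of ``f`` relative to the admissible worlds of ``d``.

    Minterms are built over the atoms of ``f`` (ordered as in the domain),
    enumerating truth assignments with T before F so that the disjunct whose
    first atom is affirmed comes first.  Minterms that are contradictions
    over the domain — assignments no admissible world realises — are dropped
    and, if ``dropped`` is given, appended to it as a provenance record.

    A formula false in every admissible world yields :data:`FALSE` (the
    explicit empty disjunction).
    """
    d.check_formula(f)
    if isinstance(f, Const):
        return f
    atom_order = [a for a in d.atom_ids if a in f.atoms()]
    keep: list[Formula] = []
    for values in product((True, False), repeat=len(atom_order)):
        assign = dict(zip(atom_order, values))
        if not evaluate(f, assign):
            continue
        literals = [
            Var(a) if v else Not(Var(a)) for a, v in zip(atom_order, values)
        ]
        minterm = make_and(literals)
        # a minterm is domain-contradictory when no admissible world extends it
        if any(
            all(w[a] == assign[a] for a in atom_order) for w in d.worlds
        ):
            keep.append(minterm)
        elif dropped is not None:
            dropped.append(minterm)
    return make_or(keep)


def substitute(f: Formula, values: Mapping[str, bool]) -> Formula:
    """Replace atoms by constants and simplify by constant propagation.

    Useful for eliminating probability-zero atoms: substituting False for an
    atom removes every conjunct/disjunct that depends on it being true.
    """
    if isinstance(f, Const):
        return f
    if isinstance(f, Var):
        if f.atom in values:
            return TRUE if values[f.atom] else FALSE
        return f
    if isinstance(f, Not):
        child = substitute(f.child, values)
        if isinstance(child, Const):
            return Const(not child.value)
        return Not(child)
    if isinstance(f, (And, Or)):
        absorbing = isinstance(f, Or)  # Or absorbs TRUE, And absorbs FALSE
        kept: list[Formula] = []
        for c in f.children:
            c = substitute(c, values)
            if isinstance(c, Const):
                if c.value == absorbing:
                    return Const(absorbing)
                continue  # identity element: drop
            kept.append(c)
        return make_or(kept) if isinstance(f, Or) else make_and(kept)
    raise LogicError(f"unknown formula node {f!r}")


# ---------------------------------------------------------------------------
# Derivations and disjunction elimination


@dataclass(frozen=True)
class DerivationStep:
    rule: str
    inputs: tuple[Formula, ...]
    output: Formula
    note: str = ""


@dataclass
class Derivation:
    """An ordered, machine-checkable proof trace.

    ``given`` are the premises; each step's output must be entailed, over
    the domain the derivation is verified against, by that step's inputs.
    """

    given: list[Formula]
    steps: list[DerivationStep] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def conclusion(self) -> Formula:
        if not self.steps:
            raise LogicError("derivation has no steps")
        return self.steps[-1].output

    def verify(self, d: Domain) -> bool:
        """Check every step is sound over the domain."""
        return all(entails(step.inputs, step.output, d) for step in self.steps)

    def to_text(self, render: Callable[[Formula], str] = repr) -> str:
        lines = ["Given:"]
        for i, g in enumerate(self.given, 1):
            lines.append(f"  ({i}) {render(g)}")
        lines.append("Steps:")
        for i, s in enumerate(self.steps, 1):
            lines.append(f"  {i}. [{s.rule}] {render(s.output)}")
            if s.note:
                lines.append(f"     note: {s.note}")
        for wmsg in self.warnings:
            lines.append(f"  warning: {wmsg}")
        lines.append(f"Conclusion: {render(self.conclusion)}")
        return "\n".join(lines)


def disjunction_eliminate(
    dnf: Formula,
    negated_disjuncts: Sequence[Formula],
    d: Domain,
) -> tuple[Formula, Derivation]:
    """Eliminate disjuncts of ``dnf`` refuted by the given premises.

    A premise eliminates a disjunct when the two are jointly unsatisfiable
    over the domain, i.e. the premise entails the disjunct's negation —
    matching is semantic, not syntactic, so differently rendered but
    equivalent premises still cut.  One elimination step is recorded per
    premise; a premise that cuts nothing leaves a warning in the trace, and
    eliminating every disjunct raises :class:`InconsistentPremisesError`.
    """
    d.check_formula(dnf)
    current = list(disjuncts(dnf))
    deriv = Derivation(given=[dnf, *negated_disjuncts])
    for premise in negated_disjuncts:
        d.check_formula(premise)
        previous = make_or(current)
        survivors = [dj for dj in current
                     if is_satisfiable(And(premise, dj), d)]
        if len(survivors) == len(current):
            deriv.warnings.append(
                f"premise {premise!r} eliminated no disjunct"
            )
        if not survivors:
            raise InconsistentPremisesError(
                "premises eliminate every disjunct: inconsistent premise set"
            )
        current = survivors
        deriv.steps.append(
            DerivationStep(
                rule="disjunction_elimination",
                inputs=(previous, premise),
                output=make_or(current),
            )
        )
    if not deriv.steps:
        deriv.steps.append(
            DerivationStep(rule="reiteration", inputs=(dnf,), output=make_or(current))
        )
    return make_or(current), deriv


# ---------------------------------------------------------------------------
# JSON serialization


def formula_to_json(f: Formula) -> dict:
    """Serialize to the stable JSON AST form."""
    if isinstance(f, Const):
        return {"op": "true" if f.value else "false"}
    if isinstance(f, Var):
        return {"op": "atom", "atom": f.atom}
    if isinstance(f, Not):
        return {"op": "not", "children": [formula_to_json(f.child)]}
    if isinstance(f, And):
        return {"op": "and", "children": [formula_to_json(c) for c in f.children]}
    if isinstance(f, Or):
        return {"op": "or", "children": [formula_to_json(c) for c in f.children]}
    raise LogicError(f"unknown formula node {f!r}")


def formula_from_json(obj: dict | str) -> Formula:
    if isinstance(obj, str):
        obj = json.loads(obj)
    op = obj.get("op")
    if op == "atom":
        return Var(obj["atom"])
    if op == "true":
        return TRUE
    if op == "false":
        return FALSE
    children = [formula_from_json(c) for c in obj.get("children", [])]
    if op == "not":
        if len(children) != 1:
            raise LogicError("not requires exactly one child")
        return Not(children[0])
    if op == "and":
        return make_and(children)
    if op == "or":
        return make_or(children)
    raise LogicError(f"unknown op {op!r}")
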