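"""Shared fixtures: cause universes, domains, and an independent
brute-force formula oracle used to cross-check the logic engine."""

from __future__ import annotations

import random

import pytest

from nhst_logic.hypothesis_framework import testable_null
from nhst_logic.logic_core import And, Formula, Not, Or, Var
from nhst_logic.test_runner import TestResult

# library helpers whose names look collectable to pytest
testable_null.__test__ = False  # type: ignore[attr-defined]
TestResult.__test__ = False  # type: ignore[attr-defined]
from nhst_logic.nhst_semantics import (
    DEFAULT_UNIVERSE,
    OPEN_UNIVERSE,
    TWO_CAUSE_UNIVERSE,
    domain_for,
)


# ---------------------------------------------------------------------------
# Independent oracle: evaluates the JSON AST form recursively, sharing no
# code with nhst_logic.logic_core.evaluate.


def brute_eval(ast: dict, world: dict) -> bool:
    op = ast["op"]
    if op == "atom":
        return bool(world[ast["atom"]])
    if op == "true":
        return True
    if op == "false":
        return False
    vals = [brute_eval(c, world) for c in ast.get("children", [])]
    if op == "not":
        return not vals[0]
    if op == "and":
        return min(vals)
    if op == "or":
        return max(vals)
    raise AssertionError(f"unknown op {op}")


def random_formula(rng: random.Random, atoms: list[str], depth: int = 3) -> Formula:
    """Random formula tree over the given atoms."""
    if depth == 0 or rng.random() < 0.3:
        return Var(rng.choice(atoms))
    kind = rng.choice(["not", "and", "or"])
    if kind == "not":
        return Not(random_formula(rng, atoms, depth - 1))
    k = rng.randint(2, 3)
    children = [random_formula(rng, atoms, depth - 1) for _ in range(k)]
    cls = And if kind == "and" else Or
    return cls(*children)


@pytest.fixture(scope="session")
def universe2():
    return TWO_CAUSE_UNIVERSE


@pytest.fixture(scope="session")
def universe3():
    return DEFAULT_UNIVERSE


@pytest.fixture(scope="session")
def universe4():
    return OPEN_UNIVERSE


@pytest.fixture(scope="session")
def domain3():
    """Admissible-world domain of the default 3-cause universe with the
    standard atom vocabulary."""
    return domain_for(DEFAULT_UNIVERSE)
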