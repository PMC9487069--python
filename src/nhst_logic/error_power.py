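"""Monte Carlo demonstrations of error and power under the real hypotheses.

The generative model realises the three-cause world semantics directly:
group 1 is Normal(mu, sigma^2), group 2 is Normal(mu + delta + b, sigma^2),
where delta is the true population difference (the intervention switch) and
b a fixed additive bias offset on one group — the simplest systematic-error
model.  The ground-truth world state is read off the switches: chance is an
active cause when sigma > 0, the population difference when delta != 0,
bias when b != 0.  Each replicate runs the pooled two-sample t test and the
strict ``P < alpha`` decision rule.

Two analysts are simulated on every rejection:

* the *minimal* analyst concludes the real alternative (always sound given
  a rejection);
* the *rigged* analyst applies the conclude-H_T premise package verbatim,
  regardless of whether its premises hold in the generating world — that
  unconditional leap is precisely the conflation under study.

A *justified* H_T conclusion is a rejection in whose generating world the
package's premises are actually true; only then does disjunction
elimination soundly reach H_T.  The justified events are a subset of the
rejections by construction, which is the event-inclusion form of the
orderings P(conclude H_T) <= P(conclude H_A) and
power-to-conclude-H_T <= power-to-conclude-H_A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .hypothesis_framework import preset_package
from .logic_core import evaluate
from .nhst_semantics import (
    BIAS,
    CHANCE,
    POPULATION_DIFFERENCE,
    ConfigurationError,
    WorldState,
    atom_truth,
    spec_from_id,
)
from .test_runner import SampleData

__all__ = [
    "GenerativeConfig",
    "SimulationSummary",
    "OrderingReport",
    "MisuseError",
    "true_world",
    "generate_dataset",
    "simulate_pvalues",
    "estimate_type1",
    "estimate_power",
    "ordering_report",
]


class MisuseError(ValueError):
    """A simulation routine was called on a config outside its contract."""


@dataclass(frozen=True)
class GenerativeConfig:
    """Configuration of the two-group generator.

    n: per-group sample size; mu: baseline mean; sigma: noise sd (>= 0);
    delta: true population difference; bias: additive offset on group 2;
    replicates: Monte Carlo replicates; seed: RNG seed; alpha: level.
    """

    n: int = 16
    mu: float = 0.0
    sigma: float = 1.0
    delta: float = 0.0
    bias: float = 0.0
    replicates: int = 10_000
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigurationError("n must be at least 2 per group")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be positive")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be non-negative")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must lie strictly in (0, 1)")


def true_world(c: GenerativeConfig) -> WorldState:
    """Ground-truth world state implied by the generator switches."""
    active = set()
    if c.sigma > 0:
        active.add(CHANCE)
    if c.delta != 0:
        active.add(POPULATION_DIFFERENCE)
    if c.bias != 0:
        active.add(BIAS)
    if not active:
        raise ConfigurationError(
            "sigma, delta and bias all zero: no cause can produce a sample "
            "difference, so no admissible world exists"
        )
    return WorldState(population_equal=c.delta == 0, active_causes=frozenset(active))


_H0_WORLD = WorldState(True, frozenset({CHANCE}))


def generate_dataset(
    c: GenerativeConfig, rng: np.random.Generator
) -> tuple[SampleData, WorldState]:
    """Draw one two-group dataset and its ground-truth world."""
    world = true_world(c)
    g1 = c.mu + c.sigma * rng.standard_normal(c.n)
    g2 = c.mu + c.delta + c.bias + c.sigma * rng.standard_normal(c.n)
    return SampleData("means", groups=(g1, g2)), world


def simulate_pvalues(
    c: GenerativeConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Two-sided pooled-t P-values for all replicates (vectorised).

    Equivalent to running :func:`~nhst_logic.test_runner.t_test` on each
    dataset from :func:`generate_dataset`; the array forms let the default
    10,000 replicates run in well under a second.
    """
    true_world(c)  # validate the config has an admissible world
    rng = rng if rng is not None else np.random.default_rng(c.seed)
    reps, n = c.replicates, c.n
    if c.sigma == 0.0:
        # degenerate noiseless draws: the t test is a sign check
        diff = c.delta + c.bias
        return np.zeros(reps) if diff != 0 else np.ones(reps)
    # draw in the same stream order as per-replicate generate_dataset calls
    draws = rng.standard_normal((reps, 2, n))
    g1 = c.mu + c.sigma * draws[:, 0, :]
    g2 = c.mu + c.delta + c.bias + c.sigma * draws[:, 1, :]
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1, v2 = g1.var(axis=1, ddof=1), g2.var(axis=1, ddof=1)
    df = 2 * n - 2
    sp2 = ((n - 1) * v1 + (n - 1) * v2) / df
    t = (m1 - m2) / np.sqrt(sp2 * (2.0 / n))
    return 2.0 * stats.t.sf(np.abs(t), df)


def _premises_true_in(world: WorldState, pkg_name: str = "table3_conclude_HT") -> bool:
    pkg = preset_package(pkg_name)
    assignment = {}
    for premise in pkg.premises:
        for atom_id in premise.atoms():
            assignment[atom_id] = atom_truth(spec_from_id(atom_id), world)
    return all(evaluate(p, assignment) for p in pkg.premises)


def _rate_se(p: float, n: int) -> float:
    return math.sqrt(p * (1.0 - p) / n)


@dataclass
class SimulationSummary:
    """Empirical rates for one generative configuration.

    All rates live in [0, 1]; each carries the binomial Monte Carlo
    standard error sqrt(p(1-p)/reps).  ``reject_flags`` and
    ``conclude_ht_flags`` retain the per-replicate events for audit, with
    conclude_ht_flags a subset of reject_flags by construction.
    """

    config: GenerativeConfig
    world: WorldState
    reps: int
    ha_true: bool
    ht_true: bool
    premises_sound: bool
    reject_rate: float
    reject_se: float
    type1_rate: float | None
    type2_rate: float | None
    power: float | None
    conclude_ha_rate: float
    conclude_ht_rate: float
    mistaken_ht_rate: float
    mistaken_ha_rate: float
    reject_flags: np.ndarray = field(repr=False)
    conclude_ht_flags: np.ndarray = field(repr=False)

    def rate_se(self, rate: float) -> float:
        return _rate_se(rate, self.reps)


def _summarize(c: GenerativeConfig) -> SimulationSummary:
    world = true_world(c)
    pvals = simulate_pvalues(c)
    reject = pvals < c.alpha
    reps = c.replicates
    reject_rate = float(reject.mean())

    ha_true = world != _H0_WORLD
    ht_true = (not world.population_equal) and (
        world.active_causes == {POPULATION_DIFFERENCE}
    )
    premises_sound = _premises_true_in(world)
    conclude_ht = reject & premises_sound  # justified H_T conclusions
    # the rigged analyst concludes H_T on every rejection; it is mistaken
    # whenever H_T is false in the generating world
    mistaken_ht = reject_rate if not ht_true else 0.0
    mistaken_ha = reject_rate if not ha_true else 0.0

    return SimulationSummary(
        config=c,
        world=world,
        reps=reps,
        ha_true=ha_true,
        ht_true=ht_true,
        premises_sound=premises_sound,
        reject_rate=reject_rate,
        reject_se=_rate_se(reject_rate, reps),
        type1_rate=reject_rate if not ha_true else None,
        type2_rate=1.0 - reject_rate if ha_true else None,
        power=reject_rate if ha_true else None,
        conclude_ha_rate=reject_rate,
        conclude_ht_rate=float(conclude_ht.mean()),
        mistaken_ht_rate=mistaken_ht,
        mistaken_ha_rate=mistaken_ha,
        reject_flags=reject,
        conclude_ht_flags=conclude_ht,
    )


def estimate_type1(c: GenerativeConfig) -> SimulationSummary:
    """Empirical type I error rate under the true-null world.

    The config must generate the testable-H0 world (population equal,
    chance the only cause): delta = 0, bias = 0, sigma > 0.
    """
    if true_world(c) != _H0_WORLD:
        raise MisuseError(
            "estimate_type1 requires the H0 world (delta=0, bias=0, sigma>0); "
            f"got {true_world(c)}"
        )
    return _summarize(c)


def estimate_power(c: GenerativeConfig) -> SimulationSummary:
    """Reject rate and conclusion decomposition under a non-null world."""
    if true_world(c) == _H0_WORLD:
        raise MisuseError(
            "estimate_power requires a world in which H0 is false; "
            "use estimate_type1 for the null world"
        )
    return _summarize(c)


@dataclass
class OrderingReport:
    """Per-config summaries plus verification of the conflation orderings.

    ``inclusion_ok`` asserts, replicate by replicate, that every justified
    H_T conclusion is also an H_A conclusion; ``strict_gap_configs`` lists
    the indices where P(conclude H_A) strictly exceeds P(conclude H_T).
    """

    summaries: list[SimulationSummary]
    inclusion_ok: bool
    strict_gap_configs: list[int]

    def to_rows(self) -> list[dict]:
        rows = []
        for s in self.summaries:
            rows.append(
                {
                    "n": s.config.n,
                    "sigma": s.config.sigma,
                    "delta": s.config.delta,
                    "bias": s.config.bias,
                    "alpha": s.config.alpha,
                    "world": s.world.describe(),
                    "reject_rate": s.reject_rate,
                    "conclude_ha_rate": s.conclude_ha_rate,
                    "conclude_ht_rate": s.conclude_ht_rate,
                    "mistaken_ht_rate": s.mistaken_ht_rate,
                    "mistaken_ha_rate": s.mistaken_ha_rate,
                    "mc_se": s.reject_se,
                }
            )
        return rows


def ordering_report(grid: Sequence[GenerativeConfig]) -> OrderingReport:
    """Run a grid of configurations and verify the orderings empirically.

    For every config: the justified-H_T events are a subset of the
    rejection events (exact, per replicate); hence empirically
    P(conclude H_T) <= P(conclude H_A) and, conditionally on H0 being
    false, P(fail to conclude H_T) >= P(fail to conclude H_A).
    """
    if not grid:
        raise ConfigurationError("ordering_report requires a non-empty grid")
    summaries = [_summarize(c) for c in grid]
    inclusion_ok = all(
        bool(np.all(s.conclude_ht_flags <= s.reject_flags)) for s in summaries
    )
    strict = [
        i
        for i, s in enumerate(summaries)
        if s.conclude_ha_rate > s.conclude_ht_rate
    ]
    return OrderingReport(
        summaries=summaries,
        inclusion_ok=inclusion_ok,
        strict_gap_configs=strict,
    )
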