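# Methods

## The model

`nhst-logic` formalises the popular "group difference" presentation of
null hypothesis significance testing (NHST) in propositional calculus and
checks every step of that formalisation by exhaustive enumeration over a
finite model.

The carrier of the semantics is the **world state**: a pair
`(population_equal, active_causes)` where `population_equal` says whether
the population parameters really are equal (μ₁ = μ₂, p₁ = p₂, ρ = 0, …)
and `active_causes` is the non-empty set of causes that produced the
observed difference between the sample statistics. Two structural
constraints define admissibility:

1. `population_equal` holds exactly when `population_difference` is **not**
   among the active causes. This single invariant is what makes
   "(μ₁ ≠ μ₂) ∧ [(x̄₁ ≠ x̄₂) due to chance alone]" a contradiction; no
   extra axiom is needed.
2. `active_causes` is never empty. Exact equality of two sample means from
   continuous data is a probability-zero event, so an observed difference
   always exists and something produced it. The reserved `sample_eq` atom
   is consequently false in every admissible world, and
   `simplify_sample_equality` eliminates it from any formula by constant
   propagation.

A **cause universe** closes the model. The default is
`{chance, bias, population_difference}` — the three-cause model in which
sampling noise, systematic error and a real effect can act alone or in
combination. A universe with k causes has (2^(k−1) − 1) + 2^(k−1)
admissible worlds (3, 7, 15 for k = 2, 3, 4). Two other universes ship:
the idealised two-cause model `{chance, population_difference}` and the
open four-cause model adding `other`, an unspecified further cause.

All logical notions — equivalence, contradiction, tautology, DNF,
entailment — are **relative to a domain** of admissible worlds, because
the equivalences between hypothesis forms hold only under the
sample-space constraints above. A free Boolean domain is available for
ordinary truth-table work. Everything is decided by exhaustive
enumeration; the domains here never exceed a few dozen worlds, so no SAT
machinery is used (a deliberate non-goal).

## Hypotheses

* **Testable null** H₀ = `pop_eq ∧ due_alone(chance)`. The P-value is
  computed from the test statistic's distribution *under this
  conjunction*; the bare equality proposition `pop_eq` is not testable by
  the decision rule alone: eliminating the chance-alone conjunct leaves
  its other refinement `pop_eq ∧ ¬due_alone(chance)` satisfiable, so
  `¬pop_eq` is never entailed (this non-rejectability is a test).
* **Real alternative** H_A = ¬H₀ — the negation of the *entire*
  conjunction. This is the only alternative making the pair exhaustive;
  `validate_pair` classifies any other pairing (`false_dichotomy`,
  `overlapping`) and exhibits concrete witness worlds.
* **Research hypothesis** H_T = `¬pop_eq ∧ due_alone(population_difference)`.
  It is one disjunct of H_A's DNF, located by semantic matching
  (`locate_research_hypothesis` reports `equal` or `contained`).

### DNF expansions

`to_dnf` produces minterm DNFs over a formula's own atoms, dropping (and
recording) minterms no admissible world realises. The named regroupings
of H_A used by the premise packages (`chance`, `research`, `bias`,
`bias_alone`) introduce refined attribution atoms; each is verified
equivalent to ¬H₀ over its domain before use. Canonical disjunct order:
population-equal disjuncts first, the H_T disjunct last, otherwise
stable — keeping H_T as the final disjunct of every expansion, the
layout the presets and reports rely on.

The two-disjunct `chance` expansion is faithful over any universe with a
second non-effect cause (the default three-cause model). Over the closed
two-cause universe its equal-population disjunct has no world and is
dropped, which is correct there; the two-disjunct display should be read
against a model that admits bias-like causes. The `bias` expansion used
by the "assume no bias only" package keeps the disjunct
`pop_eq ∧ not_due_to_bias_nor_chance_alone`, which requires the open
four-cause universe to be satisfiable; that package therefore defaults
to the open universe, and over the closed three-cause model the same
premise semantics collapse the conclusion to
H_T ∨ (¬pop_eq ∧ due_to_exactly(effect, chance)).

### Attribution atoms

Six interpretations cover every phrase that occurs: `due_to_alone(c)`
(active = {c}), `due_to(c)` (c ∈ active), `due_to_exactly(S)`
(active = S), `not_due_to_alone_nor_chance_alone(c)`
(active ∉ {{c}, {chance}}), `not_due_to_nor_chance_alone(c)`
(c ∉ active and active ≠ {chance}), plus the population-equality and
sample-equality atoms. Negative phrases like "not due to chance alone"
are `¬due_to_alone(chance)` at the formula level; the two *nor*-forms are
single atoms because their scope is a unit in the source phrasing.

## Derivations

`disjunction_eliminate` removes a disjunct when a premise is jointly
unsatisfiable with it over the domain — semantic matching, so differently
rendered but equivalent premises still cut. Each premise contributes one
recorded step; a premise that cuts nothing leaves a warning in the trace
and eliminating everything raises an inconsistency error. `Derivation.verify`
re-checks every step's entailment by enumeration, so every shipped
derivation is machine-checked rather than asserted. The procedure
commutes: premise order, and whether premises are applied before or after
the rejection step, cannot change the surviving disjunct set (tested).

Preset premise packages: `minimum_axiom_set` (no premises — the
conclusion is H_A itself), `table3_conclude_HT` (two premises ruling out
every combination in which chance plays a role → exactly H_T),
`table3_no_bias_only` (the single no-bias premise → a three-way
disjunction strictly wider than H_T), `table3_conclude_HB` (a premise
pair rigging the bias-alone hypothesis). The package deliberately does
not adjudicate which premises are scientifically warranted; it makes the
ledger explicit.

## Decision rule and reporting

The decision layer accepts exactly one axiom: reject H₀ iff P < α
(strict; P = α fails to reject). On rejection the licensed conclusion is
the real alternative, i.e. "the data were not due to chance alone", with
H_T flagged as one disjunct; on failure to reject, the only statement is
that H₀ was not rejected — the strings "accept H0"/"accept the null"
never occur in any rendered output, and a test audits this.

Tests are two-sided only (the hypothesis pairs here are two-sided).
Defaults: pooled (Student) two-sample t for means, matching the textbook
presentations being analysed, with Welch behind a flag; Pearson
chi-squared without continuity correction (Yates behind a flag on 2×2);
Pearson correlation with its t-based P-value. Statistics are computed
from their textbook formulas with scipy distributions supplying tail
areas; the test suite cross-checks them against scipy's packaged tests to
1e-10, keeping implementation and oracle separate. α has no privileged
default in the source material; the CLI default of 0.05 is a
convention, surfaced as a flag. Missing CSV values are dropped with a
logged count, never imputed. Zero-variance data raise a degenerate-data
error unless the means differ, in which case the t statistic is ±∞ with
P = 0 (needed so the noiseless σ = 0 worlds remain simulable).

## The synthetic-data generator

`error_power` realises the three-cause model generatively: group 1 is
Normal(μ, σ²)ⁿ, group 2 is Normal(μ + δ + b, σ²)ⁿ. The ground-truth
world is read off the switches — chance active iff σ > 0, the population
difference iff δ ≠ 0, bias iff b ≠ 0 (all three zero is rejected: no
cause could produce a difference). Bias as a fixed additive offset on one
group is the simplest systematic-error model; richer bias models are out
of scope. Defaults: n = 16 per group, μ = 0, σ = 1, 10,000 replicates,
α = 0.05 — a small-sample setting where power is interesting without
being degenerate. The generator is seeded (numpy `default_rng`) and the
vectorised simulation path consumes the RNG stream in the same order as
per-replicate generation, so the two are bit-identical (tested).

Per replicate, two analysts are scored on every rejection: the *minimal*
analyst concludes H_A (always sound given a rejection); the *rigged*
analyst concludes H_T by applying the conclude-H_T premise package
verbatim, regardless of whether its premises hold in the generating
world. A H_T conclusion counts as *justified* only when those premises
are true in the generating world; justified events are a subset of the
rejections by construction. This yields the three orderings as theorems
at the event level and strict inequalities on the designed bias worlds:

* P(mistakenly accepting H_T) ≥ P(mistakenly accepting H_A) — in a
  bias-only world every rejection is a correct H_A acceptance and a
  mistaken H_T acceptance;
* P(conclude H_T) ≤ P(conclude H_A), strict whenever the premises fail;
* P(fail to conclude H_T | H₀ false) ≥ P(fail to conclude H_A | H₀ false).

Note that with σ > 0 and δ ≠ 0 the true world has causes
{chance, population_difference}, so H_T ("due to the difference *alone*")
is false in every replicate even though H_A is true — the justified
conclude-H_T rate is exactly 0 there. Only the noiseless σ = 0, δ ≠ 0
configuration reaches the pure-effect world where H_T is true; it is
supported for precisely that illustration, with the degenerate-t caveat
above.

What the generator does *not* emulate: non-normal noise, unequal
variances or group sizes, bias that interacts with the effect,
selection/measurement mechanisms behind the bias offset, and any
dependence between replicates. Passing simulations therefore demonstrate
the logical orderings under an idealised sampling model, not the
behaviour of real studies.

## Numerical and design choices

* Type I calibration is checked at α ∈ {0.01, 0.05, 0.1} against a
  3-binomial-SE band at 10,000 replicates; null P-value uniformity is
  checked at the empirical CDF points 0.05 and 0.5 with the same band.
* Power monotonicity across a δ grid is asserted up to 3 summed Monte
  Carlo SEs (stochastic ordering can invert within noise).
* Formula equality for elimination and intended-conclusion matching is
  semantic (domain equivalence), never syntactic.
* Truth-table row order follows the textbook convention (first atom
  varies slowest, T before F); world enumeration orders equal-population
  worlds first, then by subset size.
* Rendering uses Unicode (μ, x̄, p̂, ρ, ≠, ∧, ∨, ¬) with an ASCII
  fallback (`mu1 != mu2`). One bracket convention is used per scenario;
  textbook presentations mix bracket classes for the same structural
  role, so the acceptance suite's string comparisons normalise bracket
  class and whitespace while comparing every symbol and word exactly.
  The prose "generic" scenario is write-only; the symbolic scenarios
  round-trip through `parse`.
* The proportions vocabulary places the p̂ symbols in the equality slot
  and p in the attribution slot, mirroring the textbook presentation
  being formalised.

## Known limitations

* The logic is propositional over a *closed* cause universe; "other"
  causes exist only if listed. Enabling `other` alongside the
  `table3_no_bias_only` package widens its conclusion accordingly — the
  behaviour is defined by the semantics, with no external convention to
  defer to.
* Whether chance must be active whenever σ > 0 is a modelling choice
  (made affirmatively here); a world with σ > 0 but chance contributing
  nothing to the observed difference is not representable.
* No confidence-interval machinery, one-sided tests, multiple-testing
  correction, effect sizes, analytic (noncentral-t) power formulas, or
  probability logic inside formulas; the decision axiom itself
  (reject iff P < α) is taken as given, not analysed.
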