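# nhst-logic

A propositional-calculus formalisation of Null Hypothesis Significance
Testing (NHST) as it is popularly presented — in terms of differences
between groups and the research hypothesis — with every equivalence and
derivation machine-checked over a finite world-state model, plus a Monte
Carlo module demonstrating what conflating the research hypothesis with
the alternative does to type I/II error and power.

It is aimed at biostatisticians, methodologists and teachers of
statistics who want the internal logic of the textbook presentation made
precise, executable and auditable.

## The core idea

The P-value of a two-sample t test is
P(observed t or more extreme | {(μ₁ = μ₂) ∧ [(x̄₁ ≠ x̄₂) due to chance
alone]}). The hypothesis in the conditioning slot — not the bare
(μ₁ = μ₂) — is therefore the only testable null H₀. For the pair to be
exhaustive, the alternative must be the negation of that whole
conjunction:

    H₀: {(μ₁ = μ₂) ∧ [(x̄₁ ≠ x̄₂) due to chance alone]}
    H_A: ¬{(μ₁ = μ₂) ∧ [(x̄₁ ≠ x̄₂) due to chance alone]}

Over the admissible worlds (a population relation plus a non-empty set of
causes — chance, bias, the real difference — producing the observed
sample difference), H_A is equivalent to a disjunction whose *last*
disjunct is the research hypothesis H_T:

    H_A ≡ {(μ₁ = μ₂) ∧ [(x̄₁ ≠ x̄₂) not due to chance alone]}
        ∨ {(μ₁ ≠ μ₂) ∧ [(x̄₁ ≠ x̄₂) not due to (μ₁ ≠ μ₂) alone]}
        ∨ {(μ₁ ≠ μ₂) ∧ [(x̄₁ ≠ x̄₂) due to (μ₁ ≠ μ₂) alone]}   ← H_T

So a significant result licenses only "the data were not due to chance
alone"; concluding H_T requires extra premises, which the package makes
explicit, applies by disjunction elimination, and verifies step by step.
The same construction generalises to proportions (p̂, p, chi-squared) and
correlation (ρ, r) via scenario vocabularies.

The library has five modules: `logic_core` (truth tables, domain
equivalence, DNF, disjunction-elimination proof traces), `nhst_semantics`
(world states, causal-attribution atoms, rendering/parsing),
`hypothesis_framework` (hypothesis pairs, validation, premise packages),
`test_runner` (t/chi-squared/correlation tests and the asymmetric
reject / fail-to-reject decision), and `error_power` (the seeded
generative model and the conflation orderings). See `docs/methods.md`
for the model and its assumptions.

## Worked example

`demo.csv` holds two groups of eight measurements (`group,value` rows;
treatment ≈ 7.4, control ≈ 5.4):

```sh
nhst-logic analyze --data demo.csv --scenario means --alpha 0.05 \
    --premises table3_conclude_HT
```

prints

```
Test: t  statistic=-6.1435  df=14  P-value=2.5468e-05  alpha=0.05
H0 (testable): {(μ1 = μ2) ∧ [(x̄1 ≠ x̄2) due to chance alone]}
HA (real alternative): ¬{(μ1 = μ2) ∧ [(x̄1 ≠ x̄2) due to chance alone]}
HA as a disjunction: {(μ1 = μ2) ∧ [(x̄1 ≠ x̄2) not due to chance alone]} ∨ {(μ1 ≠ μ2) ∧ [(x̄1 ≠ x̄2) not due to (μ1 ≠ μ2) alone]} ∨ {(μ1 ≠ μ2) ∧ [(x̄1 ≠ x̄2) due to (μ1 ≠ μ2) alone]}
Research hypothesis H_T is disjunct 3 (equal): {(μ1 ≠ μ2) ∧ [(x̄1 ≠ x̄2) due to (μ1 ≠ μ2) alone]}
Outcome: reject H0; conclude the real alternative — the data were not due to chance alone.
Premise package 'table3_conclude_HT':
  premise (1): ¬{(μ1 = μ2) ∧ [(x̄1 ≠ x̄2) not due to chance alone]}
  premise (2): ¬{(μ1 ≠ μ2) ∧ [(x̄1 ≠ x̄2) not due to (μ1 ≠ μ2) alone nor chance alone]}
Derived conclusion: {(μ1 ≠ μ2) ∧ [(x̄1 ≠ x̄2) due to (μ1 ≠ μ2) alone]}
Intended conclusion reached.
A statistically significant result licenses only the conclusion that the data were not due to chance alone; it is not a licence to accept the research hypothesis.
```

Reading: the pooled t test rejects H₀ at α = 0.05 (P ≈ 2.5 × 10⁻⁵).
Without premises that licenses only H_A. The two premises rule out every
combination hypothesis in which chance plays a role; two steps of
disjunction elimination then leave exactly H_T, and the derivation is
verified over the three-cause world domain. Other subcommands:
`hypotheses` (print a scenario's pair and locate H_T), `validate`
(diagnose false-dichotomy pairs with witness worlds), `derive` (run a
premise package, including custom JSON packages), `simulate` (Monte
Carlo rates for a generative config), `truth-table`. Add `--ascii` for
`mu1 != mu2`-style output.

A library-level taste of the simulator:

```python
from nhst_logic import GenerativeConfig, estimate_power

s = estimate_power(GenerativeConfig(seed=3, bias=1.0, replicates=10_000))
print(s.world)              # population_equal=True, causes {chance, bias}
print(s.power)              # ≈ 0.78 — H_A is concluded often…
print(s.conclude_ht_rate)   # 0.0   — …but H_T is never justified
print(s.mistaken_ht_rate)   # ≈ 0.78 — rigging H_T is mistaken every time
```

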