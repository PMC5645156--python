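# Methods

## Model

BCV treats valuation as inference. For each attribute *i* of a choice set,
the agent assumes the reward amounts *R_{i,n}* of the available options are
draws from a Gaussian population with unknown mean *C_i*:

- prior: *C_i ~ N(μ_C, σ_C²)*,
- likelihood: *R_{i,n} ~ N(C_i, σ_R²)*,
- attributes are mutually independent in the generative model.

Rewards enter inference one at a time. At the step a reward *R* is
considered, with current posterior *N(μ̂, σ̂²)*, the conjugate update is

    g  = σ̂² / (σ̂² + σ_R²)
    V  = g (R − μ̂)              # incentive value
    μ̂ ← μ̂ + V
    σ̂² ← σ̂² (1 − g)

The variance recursion applies the same conjugate form at every step, which
is equivalent to precision addition: after *t* updates
σ̂² = 1 / (1/σ_C² + t/σ_R²). (The test suite asserts this closed form
against the recursion at 1e-10.) An option's value is the sum of its
rewards' incentive values across attributes; choice is softmax with inverse
temperature β over option values. Only the prediction errors — not the
posterior itself — carry value, which is what produces context sensitivity:
a reward considered after better rewards lands below the updated expectation
and loses value.

Presentation order is random: an independent uniform permutation of the
options per attribute, per trial, from a seeded generator. Each simulated
choice starts from the fresh prior (no carryover across trials). Whether
attributes are processed in sequence or in parallel has no effect, since
their posteriors never interact; the implementation processes them
independently.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| μ_C | prior mean of the population average (reward units) | 0 | the "default" neutral expectation; subtractive normalizer |
| σ_C² | prior variance | 1 | fixed at 1 throughout the standard simulations; only the ratio σ_R²/σ_C² matters for the gain |
| σ_R² | reward observation variance | setup-specific: {0.1, 1, 10} swept | small values magnify prediction errors; context effects require small σ_R² |
| β | softmax inverse temperature | 1 | β = 0 gives uniform choice |

σ_R² = 0 and σ_C² = 0 are rejected rather than treated as limits: the gain
and the variance recursion degenerate there, and no standard setup uses
them.

## Choice probabilities: enumeration vs Monte-Carlo

Order randomization is the only stochastic element of a trial, so the choice
distribution is the exact average of softmax distributions over all (N!)^I
per-attribute order combinations. The engine enumerates whenever that count
is within `enumeration_limit` (default 10000; the standard setups need at
most (3!)² = 36), making every in-package reproduction deterministic to
machine precision. Otherwise it samples orders with a seeded generator, in
either of two modes with identical expectation: `probability_average`
(average the softmax probabilities; lower variance; the default) or
`sampled_choice` (tally one sampled choice per trial). Standard errors are
the sample SD of per-trial probabilities, or binomial, respectively. Ratio
and difference summary metrics are computed from the averaged
probabilities.

## Experiment drivers and default grids

The standard setups are hard-wired as defaults and swept over grids chosen
to span all printed payoffs: binary high/low pair (R_H = 10, R_L = 6) over
μ_C ∈ [−6, 14] step 0.5; trinary single-attribute scan with R_3 ∈ [0, 10]
step 0.5; two-attribute decoy grid with targets A = (1, 10), B = (10, 1)
and K over [1, 10]² step 0.5; compromise triple A = (5−d, 5+d),
B = (5+d, 5−d), K = (5, 5) with d ∈ [0, 4] step 0.5. All drivers emit a
long-format table with a fixed column order (see
`bcvsim.experiments.RESULT_COLUMNS`), and the runner writes a JSON manifest
(resolved config, seed, version) sufficient for bitwise reproduction.

Similarity/attraction readouts are operationalized as the sign of
P[A] − P[B] at four probe decoys: K = (9, 2) (similar to B), its mirror
(2, 9), the dominated decoy (1, 5) near A, and its mirror (5, 1). Under
enumeration no noise threshold is needed; under MC a 3-standard-error
threshold is appropriate.

## Simulated behaviour worth noting

Two places where careful enumeration sharpens or contradicts informal
expectations about this class of models:

- **Binary-scan peak.** The preference ratio over μ_C peaks at
  (R_H + R_L)/2 = 8, not at (R_H − R_L)/2: the model is exactly mirror
  symmetric about the midpoint of the two rewards (swapping μ_C →
  (R_H + R_L) − μ_C reflects every prediction error), which the tests
  assert. The curve is bell-shaped and narrower for smaller σ_R².
- **Decoy-probe signs.** At μ_C = 0, σ_R² = 0.1 enumeration gives
  P[A] − P[B] = −0.0378 at the similarity probe K = (9, 2) and −0.0275 at
  the attraction probe K = (1, 5) — i.e. each decoy shifts preference
  toward the *nearby* target, the opposite direction from the classical
  similarity/attraction phenomena. The regime structure is nevertheless
  exactly the classical one in magnitude: the attraction-probe effect
  dominates at low prior mean (|−0.045| vs |−0.012| at μ_C = −2), the
  similarity-probe effect at high prior mean (|−0.080| vs |−0.013| at
  μ_C = +2), and both vanish monotonically as σ_R² grows through
  {0.1, 1, 10}. Because the setup is exactly antisymmetric under the
  attribute swap (P[A]−P[B] at K = (p, q) equals −(P[A]−P[B]) at
  K = (q, p); asserted at 1e-12), a sign-flipped account of this map is
  indistinguishable from a transposed display of it. The package reports
  the enumerated signs as-is; some acceptance-level checks encoding the
  classical directions therefore fail by construction, and are kept
  failing rather than inverted.
  Similarly, the trinary compromise difference at μ_C = 0, σ_R² = 0.1 is
  not strictly monotone in d: enumeration resolves a shallow dip to
  ≈ −2·10⁻⁴ over d ∈ [0.5, 1.5] (far below Monte-Carlo resolution at
  10⁵ trials, SE ≈ 1.5·10⁻³) before the rise to +0.0175 at d = 4; strict
  monotonicity does hold at σ_R² = 1, and at μ_C = +2 with σ_R² = 0.1.

## Between-choice context models

A contextual cue *O ~ N(C, σ_O²)* observed before the reward shifts the
expectation to μ̂ = g_O·O (prior mean fixed at 0, as the closed form is
derived under that assumption; a `prior_mean` argument generalizes it) and
the reward is then valued against that context-informed posterior. With two
context levels (HC above LC), sequential inference P(HC|HO) → P(LC|HO) →
P(LC|HO,LO) collapses to V(R) = K(R − τ_LO·LO − τ_HO·HO); the module
computes the factors from the variances and also exposes the step-by-step
route, asserting their equality at 1e-12. Limits behave as the structure
dictates: σ_LO² → 0 makes the low-level context a Markov blanket
(τ_HO → 0), σ_HO² → ∞ reduces the model to a single-level one with prior
variance σ_HC² + σ_LC².

### Scenario mapping

The block-design scenarios (low- vs high-average menus, high- vs
low-variance menus, and the two-level deck/deck-set design) are mapped to
the context models statically: a context's observation is the mean of its
reward menu, its reward variance is the menu's population variance (floored
at 0.01 to keep the gain well-defined for near-degenerate menus), and
observation variances default to 1. Rewards are expressed as offsets from a
base value, with the base defaulting to −1.5 so that the menus straddle the
model's zero prior mean. This matters for the variance scenario: its
ordinal signature (the smaller common reward worth more in the
high-variance context, the larger common reward worth more in the
low-variance context) requires the context-informed expectation to fall
between the two common rewards, which holds when the menus are centred near
the baseline expectation but not for menus far above it. The magnitude and
two-level signatures are base-independent. Only ordinal patterns are
asserted; the scenarios are static predictions, with no trial-by-trial
re-inference of context statistics within a block.

## What the simulations do and do not show

All inputs are generated internally from the printed payoffs and parameter
sets; there is no empirical data path. Passing tests show that the
implementation computes this model's predictions exactly (enumeration) or
consistently (seeded MC vs enumeration within 3 SE), and which qualitative
effects the model does and does not produce under the standard parameter
sets. They say nothing about fit to behavioural data, parameter learning
(μ_C, σ_C², σ_R² are given, never learned), reaction times, or
evidence-termination dynamics — all outside the model as implemented.

## Numerical contract

Softmax uses max-subtraction; exact-path assertions are at absolute 1e-10
or tighter (1e-12 for identities); MC assertions use 3 standard errors.
Test problem sizes are the standard setups themselves (≤ 3 options,
≤ 2 attributes); MC checks use 10⁴–10⁵ trials. The full suite runs in a few
seconds.
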