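# bcvsim

A simulator for the **Bayesian model of context-sensitive value (BCV)**: a
normative account of why the incentive value of a reward — and hence choice —
depends on the other options on offer and on the options experienced in the
past.

`bcvsim` is for computational cognitive scientists and decision-making
researchers who want to simulate, probe, or extend precision-weighted
prediction-error accounts of valuation: it provides the single-trial
inference core, exact and Monte-Carlo choice-probability engines, drivers for
the standard within-choice context-effect setups (single-attribute third
options; similarity, attraction and compromise decoys), and the flat and
hierarchical between-choice context models.

## The model

A choice set offers options *u₁…u_N*, each defined by reward amounts
*R_{i,n}* on attributes *i = 1…I*. The agent treats each attribute's rewards
as samples from an unknown Gaussian population:

```
C_i ~ N(μ_C, σ_C²)          (prior over the population mean)
R_{i,n} ~ N(C_i, σ_R²)      (observed reward amounts)
```

Rewards are assimilated **sequentially, in a random order per attribute**
(independently across attributes). When reward *R* is considered against the
current posterior *N(μ̂, σ̂²)*, its **incentive value** is the
precision-weighted prediction error

```
V(R) = g · (R − μ̂),    g = σ̂² / (σ̂² + σ_R²) ∈ (0, 1)
```

after which the posterior mean shifts by *V(R)* and the variance contracts
by *(1 − g)*. An option's value sums the incentive values of its rewards
over attributes, and choice follows a softmax rule with inverse temperature
β. The prior mean acts as a subtractive normalizer (rewards below
expectation acquire negative value) and the gain as a divisive one (small
σ_R² magnifies prediction errors, enabling context effects).

For between-choice effects, contextual cues (*O*, or *LO*/*HO* at two
hierarchical levels) are noisy observations of the same population mean,
yielding the closed form `V(R) = K·(R − τ_LO·LO − τ_HO·HO)` with three
normalization factors in (0, 1).

Because presentation order is the only randomness in a trial, choice
probabilities are computed **exactly** by enumerating all (N!)^I
per-attribute order combinations whenever feasible (≤ 36 in all standard
setups), or by seeded Monte-Carlo otherwise.

## Worked example

```python
import numpy as np
from bcvsim import (BCVParams, ChoiceProblem, PresentationOrder,
                    evaluate_option_set, exact_choice_probs, softmax_choice)

# one attribute, a high (10) and a low (6) reward option
problem = ChoiceProblem.single_attribute([10.0, 6.0], option_labels=("H", "L"))
params = BCVParams(prior_mean=0.0, prior_var=1.0, reward_var=0.1,
                   inverse_temperature=1.0)

trace = evaluate_option_set(problem, params,
                            PresentationOrder(np.array([[0, 1]])))
print(trace.option_values)          # [ 9.09090909 -1.47186147]
print(exact_choice_probs(problem, params).probs)  # [0.51794424 0.48205576]
```

Considered first, the reward 10 is a large positive surprise against the
zero prior (gain 1/1.1, value 9.09); the reward 6 then lands *below* the
updated expectation of 9.09 and acquires a *negative* value (−1.47) — the
first option contextualizes the second. Averaging the softmax over both
presentation orders (each order strongly favours whichever option came
first) gives the exact choice probabilities (0.518, 0.482), a choice ratio
of 1.074 in favour of the better option; the ratio grows as the prior mean
approaches the rewards on offer, peaking at μ_C = 8.

The experiment drivers return tidy tables, e.g.

```python
from bcvsim import run_compromise
df = run_compromise()
df[df.metric == "trinary_difference"].query("mu_C == 0 and sigma_R2 == 0.1")
```

shows the compromise effect P[K|A,B,K] − P[A|A,B,K] rising from 0.0 at
proximity d = 0 to 0.0175 at d = 4, while the binary control
P[K|A,K] − P[A|A,K] stays exactly zero. Every driver is also a CLI
subcommand (`bcvsim compromise --out results/compromise`), which writes
`results.csv` plus a JSON manifest sufficient to reproduce the run bitwise.

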