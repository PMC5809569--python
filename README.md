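# partworth

Analysis toolkit for **partial-profile discrete choice (conjoint)
experiments**: randomized survey design, effects-coded choice data,
latent-class conditional logit estimation, attribute importance scores,
randomized first choice share simulation, and holdout validation — with
a synthetic respondent generator for testing and power exploration.

It is written for researchers who run stated-preference studies (health
services research, implementation science, health economics, marketing)
and want a reproducible, scriptable pipeline from survey instrument to
segment-level preference shares.

## The model

Respondents choose among alternatives described by attribute levels.
With effects coding (K−1 columns per K-level attribute, the last level
coded −1), the conditional logit gives alternative j of task t the
choice probability

    P(j | t, β) = exp(x_tj' β) / Σ_m exp(x_tm' β),

and a latent-class model lets preferences differ across C unobserved
segments with shares π_c:

    L_i = Σ_c π_c Π_t P(chosen_it | β_c).

`partworth` maximizes Σ_i log L_i by multi-start EM (posterior E-step,
posterior-weighted Newton M-step), reports AIC/AIC3/BIC/CAIC/entropy R²
for model selection, bootstrap likelihood-difference tests, and Wald
tests per attribute. Part-worths expand to zero-centered level
utilities; an attribute's **importance** within a class is its utility
range as a percentage of the sum of all ranges. **Randomized first
choice** simulation perturbs utilities with attribute-level and
product-level Gumbel error over many iterations and credits each
respondent's maximum-utility profile, yielding preference shares with
Monte Carlo standard errors.

See `docs/methods.md` for assumptions, numerical choices, and
limitations.

## Worked example

The package ships a two-segment preset transcribing a published
14-attribute × 4-level instrument for choices among ways of
implementing evidence-based children's mental health practices
(segment shares 12%/88%). Computing importance scores from it:

```python
from partworth import ebp_preset, importance_scores

attributes, shares, utilities = ebp_preset()
table = importance_scores(utilities, attributes)
```

`python examples/03_importance_scores.py` prints, among other rows:

```
segment 1 (12% of respondents) — top attributes:
  1. Supervisor support for EBP: 12.8%
  2. Percent of clients benefiting: 12.3%
  3. Training focus on knowledge versus skill: 10.5%

segment 2 (88% of respondents) — top attributes:
  1. Trainers expertise and engagingness: 12.3%
  2. Active versus passive training process: 10.2%
  3. Percent of clients benefiting: 9.6%
```

Each percentage is that attribute's share of the total utility swing
within the segment: variation in supervisor support moves segment 1's
choices more than any other attribute, while segment 2 responds most to
trainer quality. A segment's 14 importances sum to 100.

The other example scripts cover the rest of the pipeline, each printing
what it computes and what the numbers mean:

- `examples/01_generate_design.py` — randomized no-overlap design with
  holdout placement and balance tallies.
- `examples/02_simulate_and_fit.py` — synthetic two-segment respondents,
  1- vs 2-class fits, model-selection table, recovered shares.
- `examples/04_share_simulation.py` — basic vs enhanced training-package
  shares and a supervisor-support sensitivity sweep.

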