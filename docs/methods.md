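# Methods

This note records the models, algorithms, numerical choices, and known
limitations behind `partworth`. It is the package's own account of its
science; every number quoted here is computed by the test suite or the
example scripts.

## The experiment being modelled

A partial-profile discrete choice experiment (DCE) presents respondents
with a sequence of choice tasks. Each task offers a small number of
alternatives (here 3), each described by the levels of a subset of the
study's attributes (here 3 of 14, each with 4 levels). Within a task,
every shown attribute takes a different level in each alternative
("no overlap", a main-effects design), and each respondent receives one
of many randomized survey versions. Two fixed holdout tasks — identical
for every respondent — are interleaved at set positions (defaults: 6 and
14 of 20) and excluded from estimation so they can serve as an internal
validity check.

## Design generation

The construction is randomized and level-balanced rather than optimized:

- Within a version, attributes cycle through a shuffled queue, so each
  attribute's show-count differs by at most one per version.
- Each shown attribute receives `alternatives_per_task` *distinct*
  levels (the no-overlap rule), chosen by preferring the levels least
  shown so far in that version (random tie-breaks), then randomly
  assigned to alternatives.
- Each version draws from an independent RNG stream derived from
  `(seed, version)`, so any version can be regenerated alone.

Commercial design optimizers additionally target D-efficiency,
prohibitions, and conditional pricing; those are out of scope. The
randomized construction reproduces the structural constraints (partial
profile, no overlap, many versions, near-uniform exposure) that the
estimation and simulation layers rely on.

## Effects coding

An attribute with K levels owns K−1 design columns. Level ℓ < K is the
unit vector on its own column; level K is −1 on all K−1 columns; an
attribute not shown in a task contributes zeros, which cancel within the
task softmax (the standard partial-profile treatment). The omitted
reference level is the *last listed* level of each attribute. Level
utilities are therefore zero-centered within each attribute, and the
last level's utility is recovered as minus the sum of the coefficients.
For the built-in 14×4 instrument the coded width is P = 14 × 3 = 42.

## Latent-class conditional logit

Respondent i in class c chooses alternative j of task t with probability
softmax_j(x_tj'β_c); membership is respondent-level, so

  log L = Σ_i log Σ_c π_c Π_t P(chosen_it | β_c).

Estimation is maximum likelihood by EM:

- **E-step** — posterior membership h_ic ∝ π_c Π_t P_it(β_c), computed
  in log space.
- **M-step** — π_c = mean posterior; each β_c takes up to 3 Newton steps
  on the posterior-weighted conditional-logit likelihood (warm-started
  from the previous iterate, step-halving on any decrease). Partial
  M-steps keep per-iteration cost low; step-halving makes the EM
  objective provably non-decreasing, which the tests assert. For C = 1
  the inner Newton runs to full convergence (the likelihood is concave).
- **Starts** — `n_starts` (default 10) independent random posterior
  initializations (rows from a flat Dirichlet), seeds derived from
  `(seed, start)`; best final log-likelihood wins, ties to the lower
  start index.
- **Convergence** — relative log-likelihood change < 1e-8 or 2000
  iterations; inner Newton stops at gradient sup-norm 1e-10.
- **Identification** — classes are reported in decreasing share order.
  Published analyses may label segments differently (e.g. a 12% group
  listed first); canonical order here is by share.
- **Penalty** — an optional ridge term (default 0) stabilizes the
  M-step for sparse data. The reported likelihood and all fit indices
  are always the unpenalized log-likelihood; vendor Bayes-constant
  "log-prior/log-posterior" accounting is deliberately not reproduced.

Standard errors are square roots of the diagonal of the inverse observed
information of the *mixture* log-likelihood at convergence, with shares
parameterized as multinomial logits; the information matrix is built by
central finite differences (ε = 1e-5 scaled) of the analytic score. The
full parameter covariance feeds two Wald tests per attribute: a
joint-zero test of its K−1 coefficients within each class (df = K−1)
and a cross-class equality test (df = (C−1)(K−1)). Singular blocks are
reported as not computable (NaN) rather than guessed.

Model selection reports, per class count: p = C·P + (C−1) parameters,
df = N − p with N the number of respondents, AIC = −2LL + 2p,
AIC3 = −2LL + 3p, BIC = −2LL + p·ln N, CAIC = −2LL + p(ln N + 1), and
entropy R² = 1 − Σ_ic(−h_ic ln h_ic)/(N ln C) (defined as 1 when C = 1;
0·ln 0 := 0). The bootstrap likelihood-difference test simulates
datasets from the fitted smaller model (class from shares, then
conditional-logit choices on the same tasks), refits both class counts
on each replicate (3 random starts by default, fewer than a headline
fit, for tractability — a deviation of unknown consequence), and
reports the proportion of replicate statistics at or above the observed
−2(LL_small − LL_large).

## Post-estimation

- **Expanded utilities**: per attribute, the K−1 coefficients plus the
  implied last level; zero-sum within attribute to machine precision.
- **Importance**: I_a = 100 · range_a / Σ range_a within a class, where
  range is max − min expanded utility; ranks are assigned by descending
  importance *before* any rounding, ties to the earlier-listed
  attribute. Importance is invariant to positive rescaling of a class's
  utilities and to per-attribute recentering.
- **Individual part-worths**: u_i = Σ_c h_ic u_c, the posterior-weighted
  mixture of class utilities — the standard latent-class individual
  estimate (the vendor method behind published individual coefficients
  is not documented; this choice is recorded here as the package's own).

## Randomized first choice

For each respondent and iteration, every expanded level utility receives
independent Gumbel(0, `attribute_error_scale`) noise (shared across
profiles that use the same level), profile totals receive independent
Gumbel(0, `product_error_scale`) noise, and the maximum-utility profile
is credited. Shares are credited fractions × 100. Limits used as
correctness oracles: both scales 0 reduces to deterministic first choice
(ties split equally); attribute scale 0 with product scale 1 is exactly
the logit model, so shares converge to the mean per-respondent softmax.

Defaults are `iterations=200_000` (total respondent-draws, split evenly
across respondents), `attribute_error_scale=1.0`,
`product_error_scale=0.0` — a common randomized-first-choice default;
the error magnitudes behind published share tables are generally
unreported, so both scales are exposed. Gumbel(0, s) is sampled via the
generator's native implementation of −s·ln(−ln U); s = 0 short-circuits
to no noise rather than a degenerate draw. Monte Carlo standard errors
come from splitting iterations into 20 batches (batch-mean standard
deviation / √20). Noise is drawn for the *full* level set rather than
only the levels a scenario uses, so sensitivity sweeps share one random
stream (common random numbers): a sweep point that changes nothing
reproduces shares bit-for-bit, and differences across sweep points
reflect the level change rather than simulation noise.

Holdout validation treats each holdout task as a scenario of its
(partial-profile) alternatives, predicts shares from individual
part-worths, and compares with observed choice percentages by mean
absolute error: MAE_t = mean over alternatives of |predicted − observed|,
overall = mean over tasks. When the choices being validated follow a
conditional-logit process (as all synthetic data here do), the
consistent simulator setting is product-only Gumbel(0, 1) error — the
two are the same model — and the validation tests use it; on the full
synthetic study replica this yields overall holdout MAE ≈ 1–2%.
Attribute-level error deliberately spreads utility noise differently
and produces flatter shares, so it is an analysis choice for scenario
simulation, not for model-consistency checks.

## Synthetic respondents

The generator draws each respondent's segment from the configured
shares, a survey version uniformly, and every choice (holdouts
included) from conditional-logit probabilities at
`scale × segment utilities` — i.e. exactly the model the estimator
assumes. Holdout tasks come from a dedicated auxiliary RNG stream so
all respondents see identical holdout options. An optional
respondent-level Gaussian jitter on utilities (default off) provides a
misspecification toggle.

The built-in preset transcribes a published two-segment solution from a
DCE on implementing evidence-based children's mental health practices:
14 attributes × 4 levels, segment shares 12%/88%, zero-centered
part-worths per segment. As printed to two decimals, a few attributes'
utilities sum to ±0.01 rather than 0; the preset recenters each
attribute exactly (ranges, and hence importance scores, are unaffected).
Default study conditions are 563 respondents, 18 experimental tasks plus
2 holdouts, 3×3 partial profiles, 999 versions, and utility scale 1.0
(the printed magnitudes; the response-error level of the original
respondents is unknowable from the publication).

What the generator does *not* emulate: response styles
(straight-lining, attribute non-attendance), learning/fatigue over the
task sequence, and any misspecification beyond the jitter toggle.
Passing recovery tests therefore show the estimator is correct and
well-identified under the assumed model at study scale — not that real
survey data are this clean.

## Recovery at study scale, and a known red line

The recovery harness simulates at study conditions, fits, matches
estimated classes to generating segments by maximal utility correlation
(Hungarian assignment), and reports share error, per-class utility
correlation, and classification accuracy. Across ten seeds, the
minority (12%) share is recovered with absolute error 0.000–0.068
(8/10 within ±0.05), the majority class's utilities correlate with
truth at r ≈ 0.997, and classification accuracy is ≈ 0.92–0.96. The
minority class's utility correlation, however, spans 0.92–0.97 with
most seeds below 0.95: with only ≈ 68 minority respondents the
maximum-likelihood standard errors are ≈ 0.15–0.24 per utility —
consistent with the published Z-values, which imply the same via
SE = U/Z — and the noise-limited correlation is 1/√(1 + SE²/σ²_u)
≈ 0.93 for utilities with spread σ_u ≈ 0.45. The acceptance test
asserting both clauses jointly in 8 of 10 seeds therefore fails (2/10
in the shipped configuration) by design of the data-generating
conditions, and is left failing rather than loosened; the effect is an
information limit of the study's own sample composition, not an
estimator defect (the same estimator reaches r > 0.99 on the majority
class and passes an exact single-class oracle equivalence at 1e-6).

## Problem sizes used in the test suite

Deterministic checks run on printed-value inputs in milliseconds. The
heavy acceptance fixture runs ten full study-scale recovery experiments
(563 respondents × 18 tasks, 10 EM starts each, ≈ 1 minute per seed).
Unit tests use reduced instruments (3–4 attributes, 40–150 respondents)
chosen to exercise every code path while keeping the default suite
fast. Share-simulation checks use the full 200,000-iteration default
where the claim concerns Monte Carlo convergence, and small iteration
counts where it does not.

## Interface choice

The package is a library plus narrative example scripts; no command-line
wrapper is shipped. The analysis is inherently interactive (fit, inspect,
re-simulate), and the importable API with `examples/` covers the
design/validate/fit/simulate workflow those scripts demonstrate.
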