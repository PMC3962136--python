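# Methods

## Problem

Given an n × p matrix of continuous molecular measurements and a
multi-class outcome (nominal or ordinal, K ≥ 2 classes), find a small
feature signature that is maximally predictive of the outcome. The
package implements constraint-based selection: the signature is the
estimated parents-and-children (PC) set of the outcome node in a
Bayesian network over the variables, retrieved by the Max-Min
Parents-and-Children (MMPC) algorithm driven by conditional independence
tests (CITs).

## The multi-class conditional independence test (MC-CIT)

The test of "X ⫫ Y | Z" compares two nested regression models of the
outcome on the *conditioning features*:

- full model: outcome ~ Z ∪ {X}
- alternative model: outcome ~ Z

For a **nominal** outcome both models are multinomial logits with the
last class as baseline; for an **ordinal** outcome both are ordered
(proportional-odds) logits with a logistic latent variable and strictly
increasing thresholds. The statistic is

    D = 2 (LogL_full − LogL_alt) ≥ 0,

referred to a chi-square distribution. Two degrees-of-freedom
conventions are offered:

- `param_diff` (default): df equals the true parameter-count difference
  between the fits — K − 1 for the multinomial model, 1 for the ordered
  model. This is the asymptotically correct reference.
- `paper_one_df`: always df = 1, matching a common simplification.

If X is constant or linearly dependent on Z, the likelihood cannot
change, so D = 0 and p = 1 exactly (the rank check is explicit, not
numerical luck). For K = 2 both model families collapse to binary
logistic regression and the test reduces exactly to the binary logistic
likelihood-ratio test; this identity is verified in the test suite.

### Alternative CITs

- **Fisher-Z**: partial correlation of X and the integer-coded outcome
  given Z via residual regressions; statistic √(n − |Z| − 3)·|atanh r|
  against the standard normal. Not assessable when n − |Z| − 3 < 1.
  Nominal classes are integer-coded in lexicographic label order; the
  test treats the outcome as interval-scaled, which is its known model
  misfit for nominal outcomes.
- **G²**: each feature is discretized into three bins (below/within/above
  mean ± one sample SD, ddof = 1); stratified G² = 2 Σ O ln(O/E) over the
  observed conditioning strata with df = (Lx − 1)(K − 1) per observed
  stratum. A power heuristic forgoes the test unless n ≥ h·df with h = 5
  by default (df counted on the nominal stratum count).

All tests share one contract: they return a p-value, the statistic, the
df, an `assessable` flag (p = 1 by convention when not assessable), the
test name and the sample count used.

## MMPC

Forward phase: starting from an empty candidate PC set (cpc), each step
computes for every remaining feature its **max-min association** — the
maximum p-value over all conditioning subsets of the current cpc up to
size `k_max` — and admits the feature minimizing that maximum, provided
it is ≤ α. Features whose maximum p-value exceeds α are permanently
discarded. Ties break on (p-value, −statistic, feature index).
Backward phase: each selected feature (reverse insertion order) is
removed if any subset of the other selected features renders it
independent of the outcome at level α.

**Unassessable-test semantics** (`unassessable` option): under the
default `"skip"`, forgone tests are excluded from the max — a feature is
judged only on the tests that could actually be assessed, and a feature
with *no* assessable test at all is excluded from the signature. Under
`"independent"`, a forgone test counts as p = 1 and immediately discards
the feature. The default follows the principle that a test the procedure
declined to run is not evidence of independence; with small samples and
the G² power heuristic the `"independent"` mode collapses every
signature to ≤ 1 feature, which contradicts the intended behaviour of
the algorithm.

Defaults: α = 0.05, k_max = 3. All (feature, conditioning-set) test
results are cached, and the multinomial fits warm-start from the cached
nested fit, which dominates the cost in high-dimensional sweeps.

## Numerical choices

- Regressors are standardized internally (mean/scale) before fitting and
  coefficients are transformed back exactly; this makes the optimization
  and the coefficient bound scale-invariant.
- Multinomial logit: damped Newton with analytic gradient and Hessian,
  step-halving line search, coefficients clipped to ±30 on the
  standardized scale (quasi-separation guard), ridge fallback on a
  singular Hessian. Rank-deficient columns are dropped greedily against
  the columns already kept (tolerance 1e−9 on the normalized Gram
  residual).
- Ordered logit: L-BFGS-B with analytic gradient; threshold monotonicity
  enforced by the parametrization μ_j = μ_1 + Σ exp(δ).
- Intercept-only models use the closed form Σ n_k ln(n_k/n).
- Chi-square and normal tail probabilities use `scipy.special` primitives.

## Synthetic generators

- `gen_categorical_dataset`: X ~ N(0, I); nominal outcome drawn from a
  multinomial logit whose nonzero coefficients (magnitude =
  `effect_size`, sign alternating over feature and class) sit on
  `n_relevant` seed-chosen columns. Default effect size 1.0 (a plausible
  standardized log-odds per relevant feature).
- `gen_ordinal_dataset`: latent score X_rel·β + logistic noise cut by
  thresholds; default thresholds at the logistic quantiles giving equal
  class marginals under the null.
- `gen_null_triplet`: X loads on Z (weight w = 0.7) plus unit noise, the
  outcome depends only on Z — X ⫫ Y | Z holds by construction while the
  marginal X–Y association is strong. This is the calibration harness
  for the conditional null.
- `gen_bn_fixture`: random sparse DAGs (expected degree 2.5) with a
  linear-Gaussian mechanism and a multinomial-logit outcome, plus an
  exact d-separation oracle CIT. By default fixtures are resampled until
  every non-neighbor of the outcome is d-separable from it by a subset
  of the outcome's own PC set of size ≤ 3 — the regime in which MMPC's
  one-sided subset search is provably exact, so oracle-driven selection
  can be held to *exact* PC recovery.

All generators are deterministic given their seed and resample until
every class appears at least once.

## Evaluation protocol

Stratified nested cross-validation: the inner loop scores every
(selection method × parameter × classifier × parameter) combination by
mean inner-fold accuracy and the winner is refit on the outer training
fold; ties prefer fewer selected features, then the simpler classifier.
If a method selects zero features on a fold, the fold falls back to the
trivial modal classifier (logged). The trivial classifier is always
reported as a baseline. Methods are compared on pooled
outer-fold predictions with an exact paired binomial (McNemar-style)
test — two-sided by summing all outcomes with probability no larger
than the observed one under Binomial(b + c, ½), with a tail-doubling
variant available — and signature sizes with a two-sample t-test on the
per-fold counts.

## Scaled problem sizes and known limitations

Replicate counts in the acceptance tests and script are scaled to run
on one CPU in minutes; the scaling is a deliberate budget choice:

- the planted-signal check (n = 300, p = 10,000) runs 6 replicates in
  the test suite and 3 in the script rather than 20;
- the ordinal power comparison uses 200 replicates in the suite and 100
  in the script.

Known limitations, observed in the computations the tests run:

- **False-positive count in very high dimensions.** MMPC admits a
  feature when *every* conditioning subset keeps p ≤ α, an event with
  small but nonzero probability per noise feature. With p = 10,000 noise
  features the expected number of false admissions at α = 0.05 and
  k_max = 3 is on the order of a few dozen (the per-feature probability
  is roughly 2–3 × 10⁻³ at n = 300). Recovery of the planted features is
  reliable, but total signature sizes of ~25–30 are typical at this
  scale; bounding the signature at ≤ 15 would require a smaller α, a
  higher k_max, or fewer candidate features.
- **Ordinal power vs Fisher-Z.** Under the proportional-odds generator
  with symmetric, equal-marginal thresholds, the integer-score Fisher-Z
  test is nearly efficient: its power is statistically indistinguishable
  from the ordered-logit LRT's at the scales tested. A systematic power
  advantage for the model-based test should not be expected in this
  regime; it requires threshold asymmetry or nominal-scale effects that
  break the linear score approximation.
- **Signature-size direction between MC-CIT and G².** At moderate scale
  (n = 200, p = 20) both tests select close to the true number of
  relevant features and the sign of the mean-size difference varies with
  the seed; the size gap reported for real microarray data emerges from
  small-n/high-p settings where most G² tests are forgone, not from
  this generator at this scale.
- The d-separation-exactness guarantee for MMPC holds only under the
  one-sided-recoverability condition the fixtures certify; on arbitrary
  DAGs MMPC can admit spouses that no subset of the discovered cpc
  separates.
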