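# Methods

## Scoring models

The operator-CTO score is additive: nine adverse variables worth 1 point
each (prior target-vessel CABG, blunt stump, any calcification, severe
angulation, occlusion length ≥ 20 mm, distal disease, Rentrop grade < 2,
in-stent occlusion, ostial occlusion) plus an operator credit of −1 for
annual volume ≥ 60 cases, −1 for ≥ 5 years performing, and −2 for a
previous-year success rate ≥ 90%.  All boundaries are inclusive exactly as
written, with no floating-point tolerance: a success rate of 0.8999 does not
earn the credit.  Scores stratify into tiers at ≤ 2 / 3 / 4 / ≥ 5.

Two deliberate asymmetries in the comparators are preserved rather than
harmonized:

- the operator-CTO length threshold is **≥ 20 mm** while J-CTO, RECHARGE and
  CL use **> 20 mm** — they differ only at exactly 20 mm;
- tortuosity is carried as two booleans, `bend_ge45` (any bend ≥ 45°, the
  J-CTO/RECHARGE definition) and `severe_angulation` (≥ 2 bends > 70° or one
  > 90°, the PROGRESS definition and the operator-CTO "curvature" variable),
  with `severe_angulation ⇒ bend_ge45` enforced as a type invariant since
  the second rule geometrically implies the first;
- only the CL score distinguishes severe calcification (2.0 points); the
  operator-CTO score counts any calcification.

Operator experience groups I–V cover the five observed (years, volume, rate)
combinations.  A combination outside them (a ≥ 90% operator lacking years or
volume) resolves by the success-rate criterion first and is flagged as
extrapolated, because the success-rate credit (−2) outweighs either other
criterion (−1) in the score itself.

## Synthetic cohort generator

The generator emulates the marginal structure of a 144-procedure,
10-operator registry.  Binary lesion features are independent Bernoulli
draws at configured prevalences (defaults: blunt 0.576, calcification 0.333,
bend ≥ 45° 0.910, distal disease 0.542, in-stent 0.139, ostial 0.479,
Rentrop < 2 0.319, prior MI 0.308, prior target-vessel CABG 0.007); the
target vessel is categorical (LAD 0.424, LCX 0.097, RCA 0.472, LM 0.007).
Occlusion length is a normal truncated at 0 (sd 13 mm) whose location is
calibrated so P(length ≥ 20 mm) = 0.882.  Severe variants are drawn
conditionally inside their parent flags so the implication invariants hold
by construction.

Three defaults are not printed in any registry table and were fixed once by
back-solving published score means: `severe_angulation` = 0.333 (recovers
the PROGRESS mean 1.32 exactly under the other defaults),
`prior_failed_attempt` = 0.40 (recovers the J-CTO mean 3.10), and
`calcification_severe` = 0.167 (half of any-calcification; only the CL score
consumes it).  With these choices the RECHARGE mean is also recovered
(3.25 vs 3.24 printed).  The registry's own summary tables swap
calcification and curvature between 33.3% and 91.0% in two places; the
defaults here follow the angiographic-features table (calcification 33.3%,
curvature 91.0%), which its per-tier calcification frequencies support.  A
consequence is that the operator-CTO mean on synthetic data (~1.2) sits
below the printed 1.78 — the one marginal the two readings cannot both
satisfy.

Operators: 10 profiles with fixed group counts (2, 1, 2, 3, 2) for groups
I–V, each drawn uniformly inside its group's defining box (e.g. group V:
years ∈ [5, 15], volume ∈ [60, 120], rate ∈ [0.90, 0.99]).  Cases pick a
group with probability proportional to per-group procedure counts
(5, 6, 13, 75, 45)/144, then a uniform member.

Outcomes are generated **conditionally on the difficulty tier** of the
scored case: technical success ~ Bernoulli(0.990, 0.875, 0.538, 0.250 by
tier), and procedural success = technical success AND Bernoulli(128/131).
Because success depends on features only through the tier, the generator
encodes the score's claimed gradient as ground truth; passing tests
therefore demonstrate that the machinery recovers a gradient that is present,
not that the gradient exists in real angiographic data.  Similarly, feature
independence means real-data correlations (e.g. calcification with length)
are absent, so comparator AUCs here are illustrative, not estimates.

Randomness: one root `SeedSequence`, spawned into independent substreams for
operators, features, operator assignment, and outcomes — adding a stage
never perturbs earlier draws, and identical (config, seed) gives identical
cohorts.

The AUC benchmark generator is deliberately simpler: tier ~
(103, 24, 13, 4)/144, score uniform on {0,1,2} / {3} / {4} / {5,6} within
tier, failure ~ Bernoulli(0.010, 0.125, 0.462, 0.750) by tier.  The
within-tier score distributions are a modeling choice (no within-tier
histogram is published); its exact expected AUC, by enumeration of the
discrete joint distribution, is 0.9026 — inside the published confidence
interval (0.821–0.982) for the score's discrimination.

## Evaluation statistics

- **AUC**: Mann–Whitney estimator with midrank ties, equal to the
  trapezoidal ROC area.  Orientation: the positive class is technical
  *failure* and higher scores predict it, so a useful difficulty score has
  AUC > 0.5.  Confidence intervals use the DeLong placement-variance
  estimate with a normal approximation truncated to [0, 1]; a seeded
  case-resampling bootstrap (2,000 replicates) is available as an option.
- **Calibration**: integer scores carry no probabilities, so each score is
  first recalibrated by a univariate logistic fit
  P(event) = expit(a + b·score), maximized by Newton–Raphson (tolerance
  1e-10 on the log-likelihood, cap 100 iterations, complete separation
  detected up front and flagged rather than silently returned).  The
  Hosmer–Lemeshow statistic Σ (O−E)²/(E(1−E/n)) is then computed on ten
  quantile groups of the fitted probabilities; tied probabilities stay in
  one group, duplicate cut-points collapse, df = groups − 2, and a
  degenerate df (< 1) is flagged with an undefined p-value.  Ten groups is a
  convention, not a published fact, and is configurable.
- **Agreement**: unweighted Cohen's kappa with p_e from marginal products;
  the both-raters-constant-and-identical case is defined as kappa = 1 with
  a degeneracy flag.
- **Group comparisons**: Pearson chi-square (no continuity correction),
  two-sided Fisher exact, classical one-way ANOVA (explicit SS
  decomposition so zero within-group variance yields F = 0 or an
  infinite-F flag instead of NaN), and Kruskal–Wallis with tie correction
  (all-identical data returns H = 0).  Chi-square, Fisher, the F tail and
  Kruskal–Wallis delegate to scipy.stats after degenerate-input checks.
- **Display rounding**: percentages round half-up to one decimal; AUC and
  kappa to three decimals.

## Problem sizes

The default analysis evaluates discrimination on an n = 14,400 cohort (one
hundred replicates of the 144-procedure registry), where the binomial noise
on an AUC near 0.9 is ≈ 0.01 — small enough that the score ordering is
stable across seeds.  Property suites use n = 10,000 draws for marginal
recovery (3 binomial standard errors), n = 50,000 for logistic parameter
recovery (± 0.05), and 200 replicates of n = 5,000 for the Hosmer–Lemeshow
type-I-error check.

## Known limitations

- Published per-table test statistics of the source registry (e.g. its
  ANOVA/chi-square columns) are not reproduction targets: the raw cohort is
  not deposited, and several printed statistics are not plausible F/χ²
  values.
- The tier-conditional outcome model makes the operator-CTO score the true
  data-generating variable; comparator scores are handicapped by
  construction on synthetic cohorts.
- Large-sample Hosmer–Lemeshow tests on tier-step outcome probabilities
  reject the logistic recalibration (correctly — the step function is not
  logistic); calibration conclusions at registry scale (n ≈ 144) behave
  like the published ones.
- Missing values in cohort CSVs are rejected, not imputed.
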