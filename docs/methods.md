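# Methods

## The simulation model

The package asks a sensitivity-analysis question: if no true relationship
exists between a worker's effort–reward imbalance and their mental health,
how much apparent relationship can a pessimistic response style create?

The null data-generating process treats every questionnaire item as an
independent categorical variable. A population is a subjects × 29 integer
matrix whose cells are drawn independently from per-item marginal
distributions — independence *between* items is the null hypothesis
(no stressor/health association), and independence *within* scales
deliberately discards the factor structure real instruments have (see
Limitations).

Negative affectivity is modelled as a measurement distortion with two
parameters: a subject carries the trait with probability `p_subject`, and
each of a carrier's 29 responses is independently affected with
probability `q_items` (so `q_items` is the affected fraction *on
average*, not an exact count — the set size is Binomial(29, q)). An
affected response moves exactly one level in its item's negative
direction: up for effort and GHQ items, down for reward items. A response
already at its most-negative level stays there (saturation; no
wrap-around or multi-level shifts). Because every shift pushes the ERI
ratio and the GHQ score in the same direction, the mechanism is a
worst-case common-method bias: it can only manufacture an apparent
association, never hide one.

Scoring and analysis per population: effort = sum of 6 items, reward =
sum of 11 favourably-coded items, ERI ratio = effort / (reward · 6/11),
GHQ Likert score = sum of 12 items; three OLS regressions of the
(natural) log GHQ score — on the log ratio, on the raw ratio, and on
effort and reward jointly — each with an intercept. Per (p, q) cell the
package aggregates the mean unadjusted R² and the fraction of populations
whose coefficients reach two-sided p < 0.05.

Under the null these aggregates have analytic twins used throughout the
tests: the per-coefficient significance rate is the nominal 0.05, and
E[R²] = k/(n−1) for k independent null predictors (0.334% and 0.669% at
n = 300), which also pins down that R² is the *unadjusted* coefficient of
determination (the adjusted version averages ≈ 0 under the null).

## Reference marginals

When no empirical response matrix is supplied, marginals are
reconstructed from scale-level baseline moments: effort 12.5 (SD 1.9),
reward 48.1 (SD 3.2), log GHQ score 2.29 (SD 0.20). Items within a scale
are treated as exchangeable — only scale-level moments are available, so
per-item heterogeneity is unidentifiable — and the variance splits under
item independence: each item of an m-item scale targets mean `M/m` and SD
`sqrt(S²/m)`. The GHQ baseline is given on the log scale; its raw-score
moments come from the exact lognormal formulas `mean = exp(μ + σ²/2)` and
`sd = mean·sqrt(exp(σ²) − 1)` (≈ 10.07 and 2.04), not a naive `exp(μ)`.

Each item's categorical distribution is a **discretized truncated
normal**: a normal(μ, σ) binned onto the integer levels with unit bins,
the two end levels absorbing the tails. The two parameters are solved
numerically (hybrid Powell root-finding on the two moment residuals, with
a few σ restarts) so the categorical mean matches its target within 1e−6
and the SD within 1e−4. Any two-moment family would do; this one is fixed
and deterministic for reproducibility — identical targets give
bit-identical tables. Infeasible targets fail loudly: a mean outside the
open level range, an SD above the two-point extreme bound
`sqrt((mean−lo)(hi−mean))`, or an SD below what the family can reach for
a non-integer mean each raise a calibration error naming the bound. An
(almost) zero SD with an (almost) integer mean returns the point mass.

A useful consequence of the moment matching: the implied baseline mean
ERI ratio agrees with the second-order delta-method value
`(μ_E/μ_Rc)(1 + σ_Rc²/μ_Rc²) ≈ 0.4785` (with `μ_Rc, σ_Rc` the
correction-scaled reward moments), which the acceptance tests verify by
simulation.

## Randomness and shared random numbers

One master seed governs a run. Population *i* always uses the generator
seeded by `SeedSequence(master_seed, spawn_key=(i,))`, so grid cells can
be computed in any order — or in parallel — with identical results.
Within a population, sampling consumes exactly one uniform per cell
(inverse-CDF), and the NA step *always* draws one uniform per subject and
one per cell, whether or not the draw ends up used. Fixed consumption
aligns the streams across (p, q) conditions: the same subjects are trait
carriers as p grows, and affected-item sets nest as q grows. This
shared-random-numbers coupling makes the bias exactly monotone at the
subject level (every subject's ratio and GHQ score are non-decreasing in
p and q, reward non-increasing) and makes the `q = 0` column bit-identical
across all p. It also drastically reduces Monte-Carlo noise in
cell-to-cell contrasts.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_subjects` | 300 | subjects per simulated population |
| `n_populations` | 10,000 | populations per grid cell |
| `p_grid` | 0, 0.05, 0.10, 0.20 | NA prevalence among subjects |
| `q_grid` | 0, 0.10–0.40 | mean fraction of items affected per carrier |
| `log_offset` | 0 | offset in log(GHQ + offset) |
| `sd_mode` | `pooled` | Table-2-style SD definition (see below) |
| `marginals_source` | `reference` | moment-matched marginals, or a CSV path |

The defaults are the study conditions: 10,000 populations of 300
subjects, the full 4 × 5 (p, q) product grid including the baseline row
and column.

## Numerical and design choices

- **Reward coding.** Reward responses are stored favourably coded (5 =
  most reward); a baseline reward mean of 48.1 out of 55 is attainable
  only under this orientation, and the 1–5 distress rating of the raw
  instrument is its pre-recoding form.
- **Correction factor** applied multiplicatively to the reward score
  (ratio = E/(R·6/11)), the standard Siegrist convention.
- **Log base.** Natural log for both transforms; exp(2.29) ≈ 9.9 is a
  plausible GHQ-12 Likert mean, whereas a base-10 reading would imply an
  impossible raw mean near 195.
- **GHQ zero guard.** `log_ghq` takes a configurable offset, default 0. A
  GHQ score of exactly 0 requires all 12 items at 0 (probability ≈ 1e−7
  per subject under the reference marginals). If it does occur in a
  simulated population with a zero offset, that population is re-scored
  with offset 1 and the fallback is recorded on its record; the effect on
  cell aggregates is negligible (of order one population in 10⁷).
- **Significance** is two-sided at exactly 0.05 with strict inequality;
  a p-value of exactly 0.05 (measure zero) counts as non-significant.
  For the two-predictor model the joint indicator requires *both*
  coefficients significant in the same population (≈ 0.0025 under the
  null, printing as 0.00 at two decimals).
- **Intercept always included**; the k/(n−1) null baseline holds only
  under the with-intercept convention.
- **Degenerate populations.** A zero-variance predictor (possible only
  under point-mass marginals) yields a flagged, excluded regression
  result rather than an exception, so a grid run survives; excluded
  counts are carried in the cell summary.
- **Table-2-style SDs.** The printed scale SDs (e.g. effort 1.9) are
  subject-level spreads, so the default `pooled` mode reports
  `sqrt(mean over populations of the within-population variance)`;
  the SD *of the population means* (≈ 1.9/√300 for effort) is available
  as `sd_mode="across_populations"` since the across-populations reading
  of the summary is also defensible.
- **Interpretation bands** for an observed explained variance follow the
  rule of thumb the simulation calibrates: ≤ 5% treat with caution,
  5–10% possibly NA but unlikely, ≥ 10% not likely an NA artefact.
  `interpret_r2` additionally reports the Pareto-minimal (p, q) cells
  whose simulated mean R² reaches the observed value.

## What the generator does and does not emulate

The generator reproduces scale-level means and SDs of a realistic worker
population and the null independence structure the sensitivity analysis
requires. It does **not** reproduce: inter-item correlation and subscale
factor structure (real scales have Cronbach's alpha ≈ 0.8, so real score
variances have a between-subject common component the independent-item
model lacks); any true exposure–outcome effect; item-specific NA
susceptibility (every item is equally shiftable, which overstates NA's
reach on items that are hard to misread pessimistically); or demographic
covariates. Consequently, passing tests show the *mechanism and its
calibration* are correct under the stated null model — they do not show
that the specific biased-cell numbers would transfer to a population with
a different marginal profile. The biased-cell results are therefore
checked as properties (monotonicity, dominance, identity at zero bias)
rather than as point values.

## Test and verification sizes

The test suite runs the pipeline at reduced Monte-Carlo sizes chosen so
every stochastic bound is ≥ 3 standard errors: the null-calibration
checks use 4,000 populations of 300 subjects (type-I error within
±0.0103 of 0.05; mean R² within 0.025/0.035 percentage points of the
analytic 1/299 and 2/299), the baseline ratio check reuses the same run
against the delta-method oracle (±0.005), and the shared-seed
monotonicity suite uses a coarse 3 × 3 (p, q) sub-grid at 600 populations,
where a multi-seed power check showed the coupled contrasts are far
larger than their Monte-Carlo noise (small adjacent increments on the
full 4 × 5 grid would need far more replicates to order reliably). The
acceptance script runs the full study scale, 10,000 populations, in
about a minute.

OLS itself is delegated to statsmodels; an independent normal-equations
oracle (explicit `(X'X)^{-1}X'y`, residual-variance t tests) cross-checks
coefficients, p-values and R² to 1e−10 in the tests.

## Known limitations

- Only one bias mechanism is modelled; acquiescence, extreme responding
  and social desirability are out of scope, as are continuous NA
  severity and multi-level shifts.
- The reference marginals are a moment-matched reconstruction, not the
  original population's item frequencies; biased-cell magnitudes under
  different marginals will differ (the qualitative monotone pattern will
  not).
- The GHQ is simulated directly on the 0–3 scored scale; positive/negative
  item phrasing and the binary (0-0-1-1) scoring variant are not
  modelled.
- `interpret_r2` interpolates nothing: it reports the grid cells that
  reach the observed R², so its resolution is the grid's resolution.
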