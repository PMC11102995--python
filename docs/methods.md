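# Methods

`dmindex` builds and applies contract-compliance assessment index systems
for designated medical institutions (DMIs) — healthcare providers
contracted with a medical insurance agency. This note documents the
models and procedures the package implements, the defaults and why they
were chosen, and what the synthetic generators do and do not emulate.

## The index model

An assessment index is a three-level rooted forest: level-1 *domains*
(e.g. medical service quality, medical expense control), level-2 groups,
and level-3 *leaf* indicators. Only leaves are measured directly; each
carries a direction (positive: higher raw values are better; negative:
lower is better), a normalization rule, and a data source (institution
self-report vs. administrative records). Internal-node weights are
defined as the sums of their children's weights, so a weight table is
consistent iff every node's weight matches its children's sum.

The packaged index (`table5_fixture`) is a published 6-domain / 56-leaf
DMI index together with its three weight columns: the AHP weight `w_ahp`,
the entropy-adjusted weight `theta`, and the combined weight
`w_combined`. Loading validates the hierarchy, that leaf combined
weights sum to 1 within 5e-4, and the roll-up property within 2e-4 per
node — the published columns are independently rounded to 4 decimals, so
exact equality cannot be demanded; 2e-4 is the worst case of two rounded
4-decimal columns feeding a sum. Which rule and direction each of the
56 leaves uses is not part of the published weight table; the fixture's
assignments are plausible per-indicator choices (marked as fixture-only
metadata in the YAML) that drive simulation and examples, never weight
arithmetic.

Applicability is declarative: an indicator may restrict the institution
levels/types it applies to; scoring renormalizes the retained leaves'
weights to sum to 1, which preserves relative weight ratios and keeps
scores on the 100-point scale. The packaged index marks all indicators
universally applicable, as no restriction list is published.

## Delphi screening

Experts score each candidate indicator's importance and feasibility on a
1–10 scale. An indicator is retained iff, on *both* dimensions, the
panel mean is strictly greater than 7 and the coefficient of variation is
at most 0.25. The CV uses the sample standard deviation (n−1): a
consultation panel is treated as a sample of the expert population.
Panel quality statistics:

- positive coefficient = 100 × returned/distributed questionnaires (%);
- authority coefficient Cr = (Ca + Cs)/2, the mean of the judgment-basis
  and familiarity coefficients;
- Kendall's coefficient of concordance W on within-expert mid-ranks with
  the standard tie correction, tested by χ² = m(n−1)W on n−1 degrees of
  freedom. Experts with missing scores on a dimension are dropped from W
  (logged) so the block is complete; per-indicator screening statistics
  use each indicator's non-missing scores.

## Normalization (dimensionless assignment)

Six rules map a leaf's raw value x to a standard value y ∈ [0, 1]:

| rule | input | positive direction | negative direction |
|---|---|---|---|
| binary | yes/no | 1 / 0 | 0 / 1 |
| multi_condition | k of m requirements met | k/m | k/m |
| proportional | percent p | p/100 | 1 − p/100 |
| segment | x, range [a, b] | (x−a)/(b−a), 0 outside | (b−x)/(b−a), 0 outside |
| min_max | cohort vector | (x−min)/(max−min) | (max−x)/(max−min) |
| horizontal | x, cohort mean X̄ | x/X̄ | X̄/x |

Decisions where the published description is silent:

- *Segment* "proportional value within the acceptable range" is linear
  interpolation across [a, b].
- *Multi-condition* requirements are equally weighted (no sub-weights are
  published).
- *Horizontal* ratios can exceed 1; they are clipped to [0, 1] so the
  weighted sum stays bounded by 100. x = 0 under negative direction
  (ratio → ∞) is assigned 1.0 after clipping and logged.
- A *constant min-max* cohort assigns 1.0 to everyone: a column with no
  discriminating information should not penalize anyone, and the entropy
  step independently drives such a column's weight to 0. The min-max
  direction symmetry y⁺ + y⁻ = 1 therefore holds only for non-degenerate
  cohorts.

## Combination weighting

**Subjective (AHP).** Experts compare siblings pairwise on the Saaty 1–9
reciprocal scale. Per sibling group, expert matrices are aggregated by
element-wise geometric mean (computed by symmetrizing logs, so
reciprocity is exact); the aggregation rule is a package choice — the
source workflow delegated it to desktop AHP software without stating it.
Local priorities are the principal right eigenvector, found by power
iteration to 1e-10; λ_max is the Rayleigh quotient. Consistency:
CI = (λ_max − n)/(n − 1), CR = CI/RI with Saaty's RI table for n ≤ 10;
CR is defined as 0 for n ≤ 2 (reciprocal 2×2 matrices are always
consistent) and flagged when CR ≥ 0.1. Global leaf weights are products
of local weights along root paths.

**Objective (entropy).** On the standardized m×n institution-by-leaf
matrix (all columns share scale and direction after normalization — the
entropy input is not stated in the source and this is the only choice
that makes columns comparable): value shares P_ij = x_ij/Σ_i x_ij,
entropies e_j = −k Σ_i P_ij ln P_ij with k = 1/ln m so e_j ∈ [0, 1], the
0·ln 0 ≡ 0 convention (which makes the constant-column limit exact:
e = 1, weight 0; an ε-shift alternative was rejected for blurring that
limit), difference coefficients g_j = 1 − e_j, correction coefficients
μ_j = g_j/Σg, and AHP-adjusted weights θ_j = μ_j w_j / Σ μ w.

**Blend.** W_j = ρ·w_j + (1−ρ)·θ_j with ρ = 0.5 by default. Blending
happens at leaf level and is then summed up the hierarchy: the published
weight table's internal rows agree with children-sums (within 2e-4) but
not with blends of its internal w/θ rows (off by up to 3e-3), so
leaf-level blending is the arithmetic that reproduces it.

## Scoring

Composite score = 100 × Σ_j W_j y_ij over the institution's applicable
leaves (weights renormalized to 1). The aggregation formula is implied
rather than stated in the source; a bounded weighted sum is the only form
consistent with the published score range (max 100). Domain subscores
sum to the composite by construction. Leaves with missing standardized
values are dropped per institution with weight renormalization (logged).
Cohort summaries report mean ± SD per administrative level, ownership and
institution type with a one-way fixed-effects F test per stratifier
(matching the single-F layout of published summaries; Welch was not
used); strata with n < 2 are described but excluded from the F test.
The qualification line is a contract-renewal rule: qualified iff
score ≥ threshold.

## Reliability and validity

- **Test-retest reliability:** Pearson correlation (switchable to
  Spearman) between online and on-site scores of the same institutions;
  identical vectors return exactly 1.
- **Criterion validity:** the criterion is the regulatory penalty amount;
  a valid score should correlate negatively with it. Spearman rank
  correlation (mid-ranks for ties), then an adjusted OLS of score on
  penalty plus covariates (administrative level coded ordinally,
  institution type, outpatient/inpatient visit counts and revenue), all
  variables z-scored so coefficients are standardized betas; optionally
  refit within each administrative level without the level covariate.
  The score-as-response orientation is an interpretation of the published
  regression layout and is documented as such. Near-collinear designs
  (condition number > 1e8) are flagged, not refused.

## Synthetic data

The generators produce every input with known ground truth:

- **Delphi panels** (default 20 experts, 66 candidate indicators, 10
  planted weak ones): strong indicators get planted means in (7.5, 9.3),
  weak ones in (5.5, 6.8) — straddling but staying below the mean-7
  screen — with normal expert noise (default SD 1) clamped to [1, 10].
- **Judgment matrices**: a_ij = (w_i/w_j)·exp(ε_ij) with antisymmetric
  normal ε (default σ 0.1), so reciprocity is exact and σ = 0 is the
  consistent limit.
- **Institution cohorts** (default n = 760): latent compliance c_i is
  logit-normal (logit mean 3, logit SD 1), giving a left-skewed,
  high-compliance cohort like deployed contract assessments. Each leaf's
  raw value derives from c_i through its declared rule and direction with
  additive noise (default SD 0.05 on the unit scale); discrete rules
  (binary, condition counts) draw Bernoulli/binomial at rate c_i, except
  in the noiseless limit where they take their median outcome so the
  pipeline score is a deterministic monotone function of compliance.
  The penalty amount is lognormal with its log coupled to standardized
  logit-compliance at the target correlation (default −0.15) via a
  Gaussian-copula construction — Spearman correlation is invariant to the
  monotone exp, so the closed-form coupling hits the latent target
  exactly, while measurement noise in the score attenuates the observed
  score–penalty correlation slightly below it. A target of |ρ| = 1 with
  nonzero noise is rejected as unattainable. Covariates (level,
  ownership, type mixes; visit counts and revenue scaling with level) are
  independent of compliance.

What the generators do **not** emulate: real penalty-amount or revenue
distributions beyond order of magnitude; indicator-specific measurement
error structure; missing data patterns; institutions gaming self-reports.
Passing recovery tests therefore shows the machinery is correct and has
the planned power under idealized conditions, not that a real cohort
would reproduce published cohort statistics.

## Problem sizes and numerics

Stochastic checks use 100 seeds at the deployed cohort size (n = 760,
56 leaves) and finish in a few seconds; panel and AHP recovery use the
panel sizes above. Power iteration tolerance 1e-10 (cap 10,000
iterations); reciprocity tolerance 1e-6 on input matrices; weight-sum
tolerances 1e-9 internally, 5e-4/2e-4 for the rounded published columns.
Ties in ranks use mid-ranks throughout. Degenerate inputs (constant
columns, empty applicable sets, zero-variance scores) raise structured
errors naming the offending indicator code where one exists.

## Known limitations

- The published Kendall's W / χ² table is internally inconsistent under
  χ² = m(n−1)W for any plausible indicator count, and the underlying
  expert scores are unpublished; concordance results are therefore
  verified against hand computations and an independent Friedman-test
  oracle, not against published values.
- Real cohort-level results (score distribution, retest 0.96, criterion
  R = −0.133) depend on unavailable raw data; the package demonstrates
  the estimators' correctness by parameter recovery on synthetic cohorts
  instead.
- Applicability restrictions and per-indicator rules of the published
  index are supplementary material not redistributed here; the fixture's
  assignments are documented stand-ins.
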