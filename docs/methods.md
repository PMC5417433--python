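# Methods

## The stage model

Host colonization is treated as a sequence of three conditional Bernoulli
trials per female: bark entry, phloem entry, brood establishment. Data
arrive as grouped binomials — one assay unit (a caged bark cell or a
pre-drilled phloem hole) exposes `n` beetles and records `k` successes.
For a species×stage cell the saturated maximum-likelihood estimate is

    logit p̂ = ln(k / (n − k)),   SE(logit p̂) = sqrt(1/k + 1/(n − k)),

the delta-method/observed-information standard error. Wald 95% intervals
use z = 1.96 on the logit scale and are back-transformed, giving
intervals that are asymmetric about p̂ and always strictly inside (0, 1).
At the boundary (k = 0 or k = n) the Haldane–Anscombe adjustment adds
0.5 to each cell before taking logits, and the estimate is flagged; the
reported `p_hat` remains the raw k/n, so at a boundary the interval
brackets the corrected rather than the raw point estimate.

Covariate models (species, host class, phloem thickness) are binomial
GLMs with logit link fitted by IRLS, compared by likelihood-ratio χ²
tests. Tree- and unit-level random effects are deliberately **not**
fitted: the estimation layer is fixed-effects/saturated. The downstream
integrator needs only a logit mean and SE per species×stage, which the
saturated estimates supply directly; clustered uncertainty can be
obtained by bootstrapping over trees if needed, but no variance
components are estimated. Separation is reported as a non-convergence
flag when any coefficient exceeds 15 logits; IRLS stops at a relative
log-likelihood change of 1e-10 or 100 iterations.

Whether a display proportion should pool beetles across trees or average
per-tree proportions is ambiguous for this kind of design; both
estimators are exposed (`pooled_proportion`, `per_tree_mean_proportion`)
and neither is privileged.

## Susceptibility integration

For one species with stage estimates (μ_s, σ_s), each Monte Carlo
repetition draws independent standard normals z_s, forms
p_s = logistic(μ_s + σ_s z_s), and multiplies the three probabilities.
Two design points were genuinely open and are resolved as follows:

- **Scale of multiplication.** Draws are taken on the logit scale (where
  the MLE is approximately normal) but multiplied on the probability
  scale; a product of logits has no probabilistic meaning. The
  zero-variance limit therefore recovers the plain product of the
  back-transformed means exactly.
- **Percentile convention.** The middle 95% uses linear interpolation
  between order statistics (numpy's default); the convention is a
  parameter of `truncate_middle` since nothing forces this choice.
  "Retained" draws are those strictly inside the two bounds, so a
  1000-draw run retains 950 ± 1.

Stages are drawn independently (no correlation structure). Sampling uses
`mean + se·z` with the z-matrix drawn once in canonical stage order, so
common random numbers are preserved across parameter changes — raising
one stage's logit mean raises every draw, a property the tests assert
for random parameter perturbations. Each species gets its own RNG
substream keyed by (master seed, CRC32 of the species label), making
per-species results independent of how many species are integrated and
in what order. The default 100,000 draws put the Monte Carlo error of
the middle-95% bounds well below the third decimal.

## Rank concordance

Within each year treatments are ranked by mean trap catch (rank 1 = most
attractive; ties get average ranks). The concordance statistic is
D = Σ (r1ᵢ − r2ᵢ)², with 0 ≤ D ≤ k(k²−1)/3. Small D means *similar*
rankings, so extremeness is defined as D_rand ≤ D_obs (ties count as
extreme). The Monte Carlo null randomizes **both** rankings per
repetition, and the p-value uses the add-one estimator
p = (1 + m)/(n_reps + 1), guaranteeing p ≥ 1/(n_reps+1). The exact
oracle enumerates all k! permutations with one ranking fixed; this is
equivalent to randomizing both because D depends only on the relative
permutation, an equivalence the test suite verifies by full (k!)²
enumeration at k = 4. The exact routine refuses tied ranks rather than
approximating over the wrong permutation space.

## ANOVA, transforms, mean separation, outliers

Transforms are registered per response: sqrt for trap counts and
4-allylanisole, log(y+1) for β-pinene, 3-carene, myrcene, limonene,
β-phellandrene and camphene, identity for α-pinene.

`anova_from_summary` reconstructs a balanced one-way ANOVA from group
means, SEs and common n via ms_between = n·Σ(mᵢ−m̄)²/(k−1) and
ms_within = mean(n·seᵢ²); a property test confirms it matches the
raw-data F to 1e-10 relative tolerance on random balanced datasets. This
is what makes published summary tables re-analyzable.

`blocked_anova` approximates the site/week random-effects layout with
additive **fixed** block effects and tests the treatment factor by
partial F against the blocks-only model. For balanced designs this gives
the same treatment test as the corresponding randomized-block mixed
model; the approximation is recorded in the result's `note` field. No
REML or variance components are estimated anywhere.

Mean separation is Fisher's protected LSD: pairwise t comparisons (pooled
ms_within, unequal-n LSD) are computed only when the omnibus F is
significant at α, otherwise all groups share a letter — so under the
null the letter display can never separate groups, which the suite
checks over 200 simulated null datasets. Letters come from greedy
insert-and-absorb in descending-mean order; the letter count is small
but not guaranteed globally minimal.

The outlier scan refits the (transformed, blocked) linear model once per
candidate with a one-hot indicator for that observation and flags it
when the indicator's p-value is below α/N, N the total observation count
including the candidate. The scan is single-pass in candidate order with
removal after each flag (so one gross point cannot mask the next);
order-sensitivity is inherent to that policy and the pass/removal
behavior is configurable.

## Synthetic data

The generators emulate the experimental design, not beetle biology:

- **Colonization**: for each year×species×tree×unit, success probability
  logistic(intercept + slope·thickness + tree effect + unit effect),
  with independent zero-mean Gaussian tree/unit effects on the logit
  scale and per-tree thickness from a truncated normal. Each beetle
  succeeds by thresholding its own uniform variate, a monotone coupling
  that makes "higher intercept ⇒ no fewer successes" hold exactly under
  a shared seed. Defaults: intercepts at logit(0.633)/logit(0.847)/
  logit(0.702) — the pooled stage outcomes — tree SD 0.5 and unit SD 0.3
  logits (moderate clustering typical of log assays), thickness slope 0.
  The assay design is an explicit parameter block per year (defaults:
  2 trees × 10 cells × 5 beetles in 2013; 3 trees × 2 cells × 15 in
  2014) because the published per-species exposure totals cannot be
  reconstructed from any single stated layout; the generator does not
  guess. Pairing status is recorded at the brood stage since brood
  denominators may or may not condition on male pairing.
- **Traps**: counts per site×week×treatment are gamma-Poisson with mean
  exp(log-mean + site + week effects) and gamma shape `dispersion`
  (variance μ + μ²/shape); the sqrt transform downstream therefore has
  real work to do. Defaults: log-means ordered ponderosa ≥ Scots >
  lodgepole ≈ jack ≈ red > eastern white ≈ control with means of ~1.5–6
  beetles per trap-interval, site SD 0.4, week SD 0.2, shape 1.5.
- **Chemistry**: per species×tree×compound lognormal concentrations
  (log-SD 0.5), calibrated so historical hosts carry roughly 6–8× the
  total monoterpenes of novel hosts, Scots pine keeps a historical-like
  3-carene level, and limonene/4-allylanisole stay minimal in novel
  hosts. Totals sum the seven monoterpenes and exclude 4-allylanisole
  (a phenylpropanoid).

What the generators do **not** emulate: attraction dynamics, within-week
temporal correlation, beetle mortality/re-emergence, chemotype mixtures,
or any correlation between chemistry and colonization success. Passing
tests therefore demonstrate correctness of the estimators and tests
under the assumed hierarchical binomial / gamma-Poisson / lognormal
mechanisms, not robustness to real-data violations of them.

Packaged fixture tables carry the published per-species diameter and
phloem summaries, the pooled stage counts, and the per-species
bark-entry CIs. The phloem (951/1123) and brood (590/840) success counts
are back-derived from the published percentages and totals; each is the
unique integer reproducing the printed one-decimal percentage.

## Pipeline and reproducibility

One master seed spawns named substreams (SHA-256 of "seed:name", reduced
below 2³¹) for simulation, Monte Carlo integration and the permutation
test, so any module's output can be reproduced in isolation. Every
artifact is stamped with the seed and a hash of the analysis
configuration (the output directory is excluded from the hash so the
same analysis into two directories is byte-identical). CSVs are UTF-8,
comma-separated, header row, "." decimal.

## Problem sizes

Default test and verification sizes: coverage simulations use 500–600
replicates at n = 140 (the per-stage exposure scale of the motivating
experiments); Monte Carlo property checks use 10⁵ draws; the
permutation-vs-exact comparison uses 99,999 repetitions for 20 random
rank pairs at k ≤ 7; the brute-force median oracle uses 10⁶ draws. These
sizes put simulation error well inside the asserted 3-SE bands while
keeping the whole suite in a few seconds.

## Known limitations

- No GLMM/variance-component estimation; clustered designs are analyzed
  with fixed effects (blocks) or saturated estimates, which understate
  uncertainty when clustering is strong and pooling is used.
- No quasi-likelihood overdispersion correction for the binomial fits.
- The compact letter display is greedy, not minimal.
- The exact rank test is limited to k ≤ 8 and untied rankings.
- Printed χ² values from the motivating study are not reproducible (raw
  trial-level data were never published) and are not targets anywhere.
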