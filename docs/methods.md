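# Methods

## Two-sample MR model

The package estimates the causal effect θ of an exposure X on a binary
outcome Y from two independent GWAS: per-variant exposure effects
β̂_Xj (SD units for continuous traits, log-odds for binary ones) and outcome
effects β̂_Yj (log-odds) with standard errors. Under the instrumental-variable
assumptions (relevance, independence from confounders, exclusion
restriction), β_Yj = θ β_Xj, and each harmonized variant supplies a Wald
ratio estimate of θ. Exposure-side uncertainty is ignored in the ratio SE
(first-order delta method), which is standard for instruments selected at
genome-wide significance where per-SNP F statistics are large.

### Estimators and inference

- **IVW** combines ratios with weights β̂²_Xj/σ²_Yj, equivalent to
  zero-intercept weighted least squares of β̂_Y on β̂_X with weights 1/σ²_Yj
  (both forms are implemented and agree to numerical precision; the tests
  assert it). The default SE model is multiplicative random effects: the
  fixed-effect SE (Σw)^{−1/2} times the residual standard deviation
  √(RSS_w/(n−1)). The factor is deliberately not floored at 1, so the
  estimator is exactly classical WLS; null simulations at the study scale
  show 94–95% CI coverage. A `fixed` model flag is exposed.
- **MR-Egger** adds a free intercept; the intercept's t test (n−2 df) is the
  directional-pleiotropy diagnostic. Exposure betas are re-oriented positive
  inside the fit (flipping the paired outcome betas), as the estimator
  requires. The regression is computed with centred closed-form sums rather
  than normal equations: instrument panels whose exposure betas cluster
  tightly make X'WX catastrophically ill-conditioned, and the closed form is
  exact for simple weighted regression. The residual scale is likewise
  unfloored; at 10,000 null replicates the intercept test is sized at 4.8%
  (flooring at 1, as some implementations do, makes it conservative, ~3.3%).
- **Weighted median** orders ratios and interpolates the half-weight-centred
  cumulative inverse-variance weights at 0.5. Its SE comes from a seeded
  parametric bootstrap (default 1000 draws) that redraws both studies' betas
  from normals with their reported SEs; the CI is normal-approximate around
  the point estimate. It tolerates up to half the weight on invalid
  instruments; a breakdown test with 30% contaminated SNPs verifies it
  stays near truth where IVW does not.
- **Heterogeneity**: Cochran's Q about a reference estimate with IVW
  weights, df = n−1, I² = max(0, (Q−df)/Q), chi-square p.
- **Per doubling of odds**: binary-exposure estimates are multiplied by
  ln 2 before exponentiation so the OR reads per doubling of the exposure's
  prevalence odds. Because the CI is formed on the log scale, scaling before
  or after CI construction is algebraically identical.

### Pleiotropy outlier scan

The global test statistic is RSS = Σ w_j (β̂_Yj − θ̂_(−j) β̂_Xj)² with
w_j = 1/σ²_Yj and θ̂_(−j) the leave-one-out IVW estimate. The null
distribution is simulated parametrically (default 1000 draws): both studies'
betas are redrawn about the leave-one-out predictions, and the leave-one-out
estimates are recomputed per draw (vectorized in closed form). Empirical
p-values carry a +1 correction and are floored at 1/(n_sim+1). Per-SNP
p-values from each variant's simulated squared-residual distribution are
Bonferroni-corrected across instruments before flagging at α = 0.05;
detecting one outlier among k instruments therefore requires
n_sim ≳ k/α (the tests use 2000 draws for 30–50 SNP panels). Flagged
variants are removed, IVW is re-fit, and a distortion test compares the
estimate shift against shifts from removing equally many random variants.
The global p is validated as (super-)uniform under the generator's own null.

### Multivariable MR

Direct effects conditional on competing exposures come from a zero-intercept
weighted multiple regression of outcome betas on the K exposure-beta
columns (weights 1/σ²_Yj), residual-scaled SEs, t inference on n−K df.
Instruments are the primary exposure's panel; competing-trait betas are
looked up from their summary tables and aligned to each instrument's effect
allele (sign-flipping swapped or strand-complement codings); missing lookups
are imputed as 0 and flagged, which biases that covariate's column toward
the null but leaves the primary exposure's instruments intact. K = 1
reduces exactly to univariable IVW.

### Harmonization

Exposure records are oriented so β̂_X ≥ 0 (flip beta, swap alleles,
complement the allele frequency). Outcome records are aligned to the
exposure coding: swapped allele pairs flip the outcome beta/frequency;
strand-complement pairs are matched (flagged) by default; incompatible
pairs are dropped. Palindromic variants (A/T, C/G) cannot be
strand-resolved from alleles alone, so any with either study's EAF within
0.08 of 0.5 are dropped; the band is configurable and 0 disables the rule —
the recommended sensitivity setting when comparing against analyses that
kept all palindromic SNPs. Missing EAF disqualifies a variant from the
frequency check (dropped if palindromic) and from R² computation.

### Clumping

Greedy p-value-ranked clumping against a user-supplied pairwise LD table:
defaults p < 5e-8 for index SNPs, r² > 0.001 or ±10,000 kb on the same
chromosome for exclusion. Ties break by smaller SE then rsid, making the
output invariant to input row order. Unlisted LD pairs count as r² = 0;
computing LD from a genotype reference panel is out of scope.

### Instrument strength and power

R² = Σ 2 m_j (1−m_j) β²_j / Var(Y) with m_j the minor-allele frequency and
Var(Y) = 1 for standardized traits (an approximation, warned, for binary
traits); F = R²(n−1−k)/((1−R²)k). Binary-outcome power follows the mRnd
approximation: the alternative OR maps to a linear-probability effect
b = K(OR/(1+K(OR−1))−1) with case fraction K, sampling variance
(K(1−K)−b²)/(N R²), and power is the non-central chi-square(1) tail beyond
the central α critical value. At OR = 1 this returns exactly α. By default
proxy cases count as cases (56,306 cases vs 1.4M controls), configurable.

## Synthetic data generator

Per SNP: EAF ~ Uniform(0.05, 0.95) over non-palindromic allele pairs; true
exposure beta ~ Normal(0.015, 0.013) in SD units — a deliberately wide
spread, as in real instrument panels where a few loci dominate; the defaults
give 33 SNPs a total R² ≈ 0.5% at n ≈ 941k and per-SNP F values in the
hundreds (a high-I²GX regime where Egger dilution is negligible; narrowing
the spread reproduces dilution, which is a property of weak panels, not a
bug). SEs are the standard per-allele forms 1/√(2p(1−p)n) and, for the
case-control outcome, 1/√(2p(1−p)N K(1−K)). Directional pleiotropy is
planted aligned with the exposure-increasing allele so that positive
orientation preserves its sign; balanced pleiotropy is mean-zero normal.
Outliers add a fixed log-odds offset to randomly chosen SNPs. Participant
overlap induces correlation `overlap_fraction` between the two studies'
error draws. About a third of outcome records are re-coded on the opposite
allele to exercise harmonization. The weak tail of the effect-size
distribution genuinely fails 5e-8 selection, as in a real discovery step.

What the generator does *not* emulate: LD between instruments, allele
frequency differences between studies, winner's-curse inflation of
discovery betas, population stratification, and binary-exposure liability
scale subtleties. Passing recovery tests therefore demonstrate estimator
correctness under clean two-sample sampling, not robustness to those
artifacts.

## Frailty (survival-bias) simulation

The simulation asks: if the exposure only raised mortality and never touched
the disease, how big an exposure-disease "effect" would the study design
manufacture? Steps per replicate: (1) genotypes ~ Binomial(2, EAF) for the
instrument panel; (2) exposure = genetic score + environmental noise scaled
to the configured mean/SD (drinks/week: mean 7.6, SD 8) or, for a binary
exposure, Bernoulli with log-odds logit(prevalence) + centred score;
(3) age ~ Normal(65, 10) truncated to [40, 90]; (4) survival to the current
age from a Gompertz–Makeham cumulative hazard H(t) = HR·[ct + (a/b)(e^{bt}−1)]
with c = 5e-4, a = 3e-5, b = 0.09 (≈80% survival to age 70 unexposed) and
the hazard ratio applied to the exposed stratum — above mean + 1 SD for a
continuous exposure (HR 1.12 for heavy drinking), the exposed level itself
for a binary one (HR 1.62 for current smoking); (5) disease sampled among
survivors from an age-band table of diagnosis probabilities; (6) a
case-control sample is drawn and per-SNP genotype-disease log-ORs estimated
by the score-test (discriminant) approximation
(x̄_case − x̄_control)/var(g); (7) IVW and Egger run with the known
genotype-exposure effects as the exposure side, plus a logistic
observational fit of disease on exposure.

Numerical/design choices worth noting:

- **Incidence defaults** are cross-sectional diagnosis probabilities per
  decade from age 40: 0.001, 0.003, 0.01, 0.025, 0.05 — approximate
  Parkinson's-prevalence magnitudes. They also make the default sampling
  target (56,306 cases per 6M population, i.e. ~0.94%) attainable;
  substantially lower tables would starve the case sample. Fully
  config-replaceable, as are the hazard parameters.
- **Sampling**: cases and controls are drawn uniformly from the eligible
  pools (the age skew of cases arises from the incidence table itself); if
  fewer cases exist than requested, all available are taken with a logged
  note (`require_full_sample=True` restores strict failure). Scaled-down
  configurations keep the study's case fraction.
- **Summary**: per-approach arithmetic mean OR, 2.5/97.5 replicate
  percentiles, and the geometric mean exp(mean log-OR). At reduced
  population scale the per-replicate log-OR spread is large and the
  arithmetic mean of ORs is upward-biased (Jensen); the geometric mean is
  the stable central estimate and is what comparisons use.
- **Seeding**: one master seed spawns per-replicate substreams, so any
  replicate is reproducible in isolation.
- The one-sample t test compares the replicate log-OR distribution with a
  reference MR log-OR; a degenerate distribution falls back to exact
  comparison.

Problem sizes: the test and acceptance runs use 10⁵ individuals × 200
replicates (the full-scale analysis is 6×10⁶ × 1000, a scale parameter
only — summary means agree within Monte-Carlo error). With no
exposure-mortality link the simulated IVW OR is a clean null; with the
drinks-per-week or smoking-continuation conditions the frailty-only OR
stays near 1, demonstrating that selective mortality of the magnitude
reported for these exposures cannot manufacture protective ORs of 0.6–0.8.

## Known limitations

- No LD-aware estimation: instruments are assumed independent after
  clumping, and clumping itself requires a user-supplied LD table.
- No GSMR/HEIDI, mode-based estimators, MVMR-Egger or conditional F
  statistics.
- The mRnd power formula and the R² sum are observed-scale approximations
  for binary traits.
- The frailty model is cross-sectional per age (no competing risks, no
  time-to-onset modelling), and its uncited numeric defaults (hazard
  parameters, incidence, age distribution, heavy-drinking threshold) are
  package choices exposed in configuration, so comparisons against any
  specific published frailty run are tolerance-based, not exact.
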