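# Methods

`gxediet` implements a genome-wide gene–diet interaction analysis for a
multi-study case–control consortium: dietary-exposure harmonization, SNP
quality control, per-study logistic interaction models, inverse-variance
fixed-effects meta-analysis, a conventional interaction scan at the
genome-wide level, and the two-step Cocktail procedure with weighted
hypothesis testing. Because the individual-level consortium data this kind
of analysis is run on are not publicly deposited, the package ships a
synthetic consortium generator that reproduces the statistical structure
the analysis assumes, and every stage is validated against it.

## The interaction model

Within each study, disease risk follows the logistic model

    logit P(D = 1) = β0 + βG·G + βE·E + βGE·(G × E) + γᵀC

where `G` is the allele dosage (0–2, fractional for imputed SNPs,
log-additive), `E` the harmonized dietary quartile code (ordinal 1–4,
entered as a single numeric covariate, lowest quartile as reference), and
`C` the adjustment set: age at reference, sex, total energy (when the study
recorded it), and the first three ancestry principal components. Study and
center effects are absorbed by analyzing each study separately. `βGE` is
the multiplicative interaction: the change in the per-allele log-odds per
quartile increment of intake. A "multivariable" adjustment set (BMI,
smoking, alcohol, the other dietary factors' quartile codes, when present)
is selectable in the pipeline config.

Per-study coefficients are pooled by inverse-variance fixed-effects
meta-analysis (`w_i = 1/se_i²`, pooled β = Σwβ/Σw, pooled se = (Σw)^-½)
with Wald z and two-sided normal p. Heterogeneity uses Woolf's chi-square
`Q = Σ w_i (β_i − β_pooled)²` on k−1 degrees of freedom. Studies in which a
SNP fails QC or a fit does not converge are dropped from that SNP's pooled
estimate, with `k` recorded. Confidence bounds are always `exp(β ± 1.96·se)`.

## Harmonization

Raw intakes (meats, vegetables, fruit in servings/day; fiber in g/day) are
quartile-coded from cutpoints computed in the *controls* of each study and
sex; all subjects are then coded 1–4 against their stratum's cutpoints, so
cases can never influence the coding. Cutpoints are linearly interpolated
empirical quartiles (numpy's default rule) and values exactly at a cutpoint
fall in the lower quartile — the quantile rule and tie policy are
conventions of this implementation, chosen for determinism; property tests
avoid tie-sensitive assertions, and codes are invariant under any strictly
monotone transform of intake. Studies that recorded an exposure in only 2
or 3 categories map them onto the quartile scale as {2,3} and {1,2,3}
respectively. Strata with no usable controls are excluded with a warning
record; strata with fewer than 8 controls are coded but flagged.

## Genotype QC

Filters follow consortium practice, with boundary semantics applied exactly
as stated: genotyped SNPs fail on call rate < 98% or Hardy–Weinberg
disequilibrium in controls at p < 1e-4; all SNPs fail on per-study minor
allele count ≤ 5 (MAC computed from rounded dosage totals); imputed SNPs
fail on accuracy r² ≤ 0.3. The HWE test is the exact conditional test:
given the allele counts, the probability of every heterozygote
configuration is enumerated (Levene–Haldane distribution) and
configurations no more probable than the observed one are summed.
Monomorphic SNPs return p = 1. HWE applies only to genotyped SNPs —
continuous dosages have no exact HWE distribution — and is evaluated on
controls. The test agrees with an independent exact-integer enumeration
oracle for every genotype configuration with N ≤ 200 (exhaustive sweep in
the test suite).

## Case-only test and the G–E screens

The case-only (CO) interaction test regresses the genotype on diet among
cases only: under population G–E independence and rare disease, the
genotype distribution among cases shifts per allele by `βG + βGE·E` on the
logit scale, so the diet coefficient of a per-allele logistic regression
(binomial GLM on dosage/2 with two trials, covariate-adjusted) estimates
`βGE` directly, with substantially smaller variance than the case-control
(CC) product-term test. The genome-scale path uses the asymptotically
equivalent covariate-adjusted linear regression z statistic, rescaled by
the dosage variance so the reported effect is on the interaction log-odds
scale (z and p are invariant to the rescaling); the two formulations are
cross-checked in the tests. When independence fails, the CO estimand is
biased — demonstrated in the test suite — which is why the procedure below
never pairs the CO test with the correlation screen.

Two screening statistics are computed per SNP, each per study and then
meta-combined as fixed-effects z-scores: (i) the marginal SNP–disease
association, computed as an efficient score test against the
covariates-only null model (one null fit per study serves every SNP), and
(ii) the G-on-E linear association in cases and controls combined,
covariate-adjusted.

## Conventional scan and the Cocktail procedure

The conventional scan fits the CC interaction model for every QC-passing
SNP (batched Newton–Raphson over chunks of SNPs; cross-checked against the
single-fit reference implementation to 4+ decimals) and declares
significance at 5e-8, i.e. 0.05 Bonferroni-adjusted for ~1 million
independent tests.

The Cocktail procedure:

1. **Screen** each SNP by max(|z_marginal|, |z_correlation|); ties go to
   the marginal screen (which feeds the more efficient CO test).
2. **Prune** by proximity: greedily retain the best remaining SNP and drop
   all others within ±50 kb on the same chromosome; fully deterministic
   (ties broken by chromosome, then position) and independent of input
   order.
3. **Rank and group**: retained SNPs are ranked by screen statistic and
   partitioned into groups of doubling size n_j = 5·2^(j−1) with per-test
   cutoffs α_j = α/(2^j·n_j): 0.005, 0.00125, 0.0003125, … at α = 0.05.
   Group j spends exactly α/2^j, so the infinite scheme sums to α and any
   finite scheme spends less; the final partial group keeps its nominal
   α_j (conservative). The published description of this grouping contains
   an off-by-one (a "20-SNP" third group spanning 21 ranks); the
   implementation follows the arithmetic, so group 3 covers ranks 16–35.
4. **Test**: CO when the marginal screen won, CC when the correlation
   screen won — the CO test is not independent of the correlation screen,
   and pairing them would inflate type I error. If the chosen test is not
   estimable the other is used with a `FALLBACK` flag (conservative, since
   the CC test is valid unconditionally). A SNP is significant iff its
   chosen meta-analysis p falls strictly below its group cutoff.

Whether the original analysts computed screens on pooled individual-level
data or meta-combined per-study statistics is not stated in the method's
description; this implementation meta-combines per-study statistics
throughout, the one reading consistent with the rest of the analysis.
Screens with different study coverage are pooled independently with their
own k.

## Synthetic consortium generator

The generator is first-class, tested code; its defaults are the study
conditions everything else is calibrated against.

**Design.** Ten case–control studies of unequal size totalling 9,287 cases
and 9,117 controls, sex ratios 0.40–0.60, study-specific intake means
(±15% around base values of 0.90/0.55/2.4/2.0 servings/day and 18 g/day
fiber), one study with 3-category fiber and one with 2-category vegetable
recording to exercise the coarse-questionnaire mapping. Covariates: age ~
N(62, 8), three PCs ~ N(0,1), energy ~ N(2000, 500) kcal; their values are
not reported in consortium descriptions and are configurable.

**Exposures** are a Gaussian copula with latent correlations
fruit–vegetable 0.38, fruit–fiber 0.52, red–processed meat 0.62 (the
vegetable–fiber 0.30 fills an unreported pair; meat–plant pairs are zero),
margins scaled to study mean/SD, truncated at zero, with male/female mean
shifts. Truncation attenuates the measured Pearson correlations by < 0.01
at the default means. Quartile coding downstream makes the marginal shape
immaterial.

**Genotypes.** Hard calls are drawn from Hardy–Weinberg proportions at
study-specific frequencies (a shared panel base with ±0.02 study jitter;
named SNPs can be pinned per study, e.g. the hit SNP's 0.21–0.27 spread).
Imputation noise uses a latent proxy-locus construction: a second locus in
haplotype LD r′ with the true genotype is simulated, and the dosage is the
linear predictor of the true genotype from the proxy plus a small jitter
(SD 0.04), with r′ solved in closed form so that corr²(dosage, hard call)
equals the target r² for any r² in (0, 1]; r² = 1 returns the hard call
exactly. Call rate is metadata (≥ 0.985 by default, plantable failures);
dosage matrices are complete — missingness handling is orthogonal to every
quantity this package validates. Positions place SNPs 200 kb apart across
22 autosomes, outside the pruning window, so independent SNPs stay
independent; LD beyond optional proxy pairs is out of scope.

**Retrospective sampling.** A population pool is simulated under the
logistic model with the intercept solved (Brent's method) for 5% disease
prevalence — the rare-disease regime that makes the CO≈CC equivalence
testable — and exactly n_cases/n_controls are drawn. Planted effects act on
the *true* genotype (the dosage is the noisy measurement), and exposure
effects act on pool-level sex-specific quartile codes; the analysis recodes
from sampled controls, which at 5% prevalence reproduces the pool coding up
to negligible boundary misclassification. SNPs with no planted effect are
exchangeable with respect to disease status and are simulated only for
sampled subjects — statistically exact and the main reason genome-scale
replicate simulations are cheap.

**Planted effects.** The headline configuration plants the interaction OR
1.17 per count allele per processed-meat quartile on a chromosome-10 SNP,
as a *crossing* interaction (per-allele main effect −2.5·βGE, so the SNP
has no marginal disease association at the mean quartile code — matching
the reported weak marginal screen for the hit locus). Diet main effects are
planted as conditional per-quartile log-odds calibrated (by solving the
quartile-code correlation system) so that the usual single-factor marginal
models reproduce the consortium-style estimates: red meat 1.15, processed
meat 1.11, vegetables 0.93, fruit 0.93, fiber 0.91.

**What the generator does not emulate.** Measurement error in diet,
between-study questionnaire heterogeneity, LD structure, genotyping batch
effects, and secular confounding. One consequence is visible and
documented: a clean multiplicative interaction of this strength
mathematically induces a detectable G–E correlation among cases (z ≈ 6 at
consortium scale), so the correlation screen ranks the synthetic hit
highly, whereas the real consortium observed a weak correlation screen for
its hit locus — real interactions, diluted by measurement error and
heterogeneity, need not produce the clean signature the generative model
implies. Passing tests therefore validate the *procedures* under the
model's assumptions, not the idiosyncrasies of any particular real dataset.

## Calibration results the package recomputes

All of these are computed at run time by `scripts/acceptance.py` and the
acceptance test suite, never asserted as constants:

* **FWER**: 200 complete-null consortium replicates (4 studies × 1,000
  cases + 1,000 controls, 2,000 independent genotyped SNPs, one exposure);
  the full Cocktail scan's family-wise rejection rate must not exceed the
  0.05 budget plus two binomial standard errors.
* **Exposure correlations**: fruit–vegetable and red–processed meat sample
  correlations at n = 10,000 within ±0.03 of 0.38 and 0.62.
* **Effect recovery**: 50 full-scale consortium replicates each for the
  planted interaction (mean meta OR within [1.12, 1.22] of 1.17) and the
  planted marginal red-meat effect alone (mean meta OR within [1.12, 1.18]
  of 1.15).
* **Null calibration**: interaction p-values and Woolf heterogeneity
  p-values uniform under a small-study null (KS p > 0.01 at 1,000
  replicates); genomic inflation λ of a null scan in [0.95, 1.05].

Problem sizes (2,000 SNPs, 200/50/1,000 replicates) are the package's
validation design: large enough for the Monte-Carlo error bounds above,
small enough to run on a single CPU in minutes.

## Numerical choices

* Logistic fits: statsmodels Newton MLE for single fits; the batched scan
  engine runs vectorized Newton–Raphson (chunk 128 SNPs, tolerance 1e-6 on
  the step, ridge 1e-9 to survive degenerate designs, which are then
  flagged unconverged); the final-iteration Hessian serves as the observed
  information.
* Score screen: one covariates-only null fit per study; per-SNP score
  U = Gᵀ(y − p̂), variance V with the covariate projection removed; the
  one-step estimate U/V with se V^-½ is what enters the meta-analysis.
* Collinear terms are dropped by a pivoted rank check and reported as not
  estimable; separation and non-convergence are flagged, never silent.
* p-values are floored at the smallest positive double; heterogeneity with
  k = 1 is emitted as missing, not 1.
* Determinism: every simulation takes a single integer seed, spawned into
  independent child streams; identical configs reproduce byte-identical
  outputs, and pipeline manifests record SHA-256 hashes of every table.

## Known limitations

* The CO/correlation-screen machinery assumes the ordinal quartile code is
  the analysis scale; continuous-exposure interaction tests are out of
  scope.
* No conditional logistic regression for matched designs, no
  robust/sandwich variances, no random-effects meta-analysis.
* The MAF-based exclusion mentioned alongside consortium QC has no printed
  numeric cutoff; only the MAC > 5 rule is implemented (a MAF threshold is
  configurable but off by default).
* Whether energy should enter log-transformed is unstated; raw energy is
  used and configurable.
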