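# Methods

## Model and assumptions

Two-sample MR treats genetic variants as instrumental variables for an
exposure. A variant j is a valid instrument when it (i) associates with the
exposure (relevance), (ii) is independent of exposure–outcome confounders,
and (iii) affects the outcome only through the exposure (exclusion
restriction). Under these assumptions each variant's Wald ratio
ρⱼ = β̂_outcome,j / β̂_exposure,j estimates the same causal effect, and the
estimators differ in how they defend against violations of (iii):

* **IVW** assumes all instruments valid; it is the inverse-variance-weighted
  mean of the ratios, identical to weighted least squares of outcome on
  exposure betas through the origin with weights 1/se_outcome². The
  first-order ("NOME") ratio SE se_outcome/|β_exposure| ignores exposure-side
  sampling noise; it is adequate when the exposure GWAS is precise relative
  to the causal-effect-scaled outcome noise (per-SNP F ≥ 10 enforces this).
* **MR-Egger** allows directional pleiotropy with an intercept, valid under
  the InSIDE assumption (pleiotropy independent of instrument strength).
  Exposure effects are oriented non-negative before the fit because the
  regression is not invariant to allele recoding. SEs use residual
  overdispersion floored at 1 — the convention in two-sample MR — so the
  Egger model never reports less uncertainty than its homoscedastic ideal.
* **Weighted median** is consistent while valid instruments hold > 50% of the
  weight. The point estimate interpolates the ordered ratios at normalized
  cumulative weight 0.5; the SE comes from a parametric bootstrap that
  redraws both exposure and outcome betas from their sampling distributions
  (default 1,000 replicates, mandatory seed).
* **Simple mode** takes the normal-kernel density mode of the unweighted
  ratios (plurality-valid assumption). Bandwidth is 0.9·(1.4826·MAD)·k^(−1/5)
  times a configurable factor; a zero MAD (coincident ratios) degenerates to
  the plurality value. The mode is found on a 2,048-point grid spanning the
  ratios ±3 bandwidths; the bootstrap engine is shared with the weighted
  median.
* **Bayesian weighted MR** is specified here as: β_outcome,j ~
  N(θ·β_exposure,j + αⱼ, se_outcome,j²) with pleiotropy αⱼ ~ N(0, τ²)
  marginalised analytically; priors θ ~ N(0, 1) and τ ~ half-Normal(0, 0.5).
  The (θ, τ) posterior is integrated on a dense grid (601 × 61 points,
  centred on the WLS solution, widened automatically until < 10⁻⁴ posterior
  mass sits on the grid edge), which is deterministic and avoids MCMC
  convergence concerns; `n_draws`/`seed` are accepted for interface
  stability with sampling backends. Marginalising a common τ de-weights all
  instruments together when any instrument is pleiotropic, which is what
  makes the posterior mean robust to a single high-weight outlier. The
  published analyses name this estimator without formulas; the model above
  is this package's declared specification, with priors exposed so published
  variants can be matched.

## Instrument selection and harmonization

Defaults follow the motivating study's protocol: p < 1×10⁻⁵, greedy LD
clumping excluding any pair with r² > 0.001 within 1,000 kb on the same
chromosome (most significant variant wins; ties broken by chromosome,
position, then id, so output is deterministic), F = β²/SE² ≥ 10, and an
optional blocklist of confounder-associated variants (a static file standing
where the study used interactive database lookups, which are not
reproducible). Instruments absent from the outcome GWAS are dropped and
logged; no proxy substitution is attempted. Harmonization resolves
effect/other swaps (sign flip) and strand flips (complement); palindromic
A/T and C/G variants are dropped by default, matching the study; an
`eaf_rescue` policy aligns them by allele frequency instead, keeping only
variants whose frequencies on both sides are outside 0.5 ± 0.08.

## Sensitivity analysis

Cochran's Q over the ratios drives a single fixed/random-effects decision per
analysis (random iff Q's p < 0.05) that is reused by every downstream IVW
call, including leave-one-out. Exactly collinear fits have zero residuals and
a zero intercept; the intercept test then reports p = 1 (no expressible
evidence against the null) rather than an undefined statistic.

MR-PRESSO follows the three-stage scheme: (1) global test comparing the
observed weighted leave-one-out residual sum of squares against its
distribution over n_sim parametric simulations under the no-pleiotropy model
(both betas redrawn); (2) per-variant outlier test of each observed squared
residual against its own simulated distribution, Bonferroni-corrected over k,
flagged below 0.05; (3) distortion test comparing the relative change between
full and outlier-corrected IVW estimates against changes obtained by removing
outlier-sized resamples of the inlier set. Empirical p-values use the
(r + 1)/(n + 1) construction, so the minimum resolvable p is 1/(n_sim + 1) —
n_sim = 1,000 (default) resolves the Bonferroni threshold up to k = 50.
Simulation count and seed are exposed because the source protocol states only
the significance level.

## Mediation and gating

Candidate exposures pass screening iff the primary estimator (IVW) has
p < α and every confirmation estimator (weighted median by default) has
p < α with sign agreement; the first failed gate is recorded
(`primary-p`, `confirm-p`, `sign-disagreement`, `no-instruments`). Reverse-MR
gates require the reverse estimate's p ≥ 0.05 on all three edges
(outcome→exposure, mediator→exposure, outcome→mediator) before mediation is
attempted; zero selectable reverse instruments pass with a warning since they
carry no evidence of reverse causation. For the mediator→outcome step,
variants already associated with the exposure (below the selection
p-threshold) are excluded from the mediator instrument set, mirroring the
study's exclusion of variants "already associated with the pathway" and
keeping β₂ identified by mediator-specific instruments.

All decomposition arithmetic is on the log-OR scale, where the identities
indirect = β₁β₂, direct = total − indirect are exact. The indirect-effect SE
is first-order Sobel, √(β₂²se₁² + β₁²se₂²); the proportion CI propagates
var(indirect/total) to first order treating the two as independent
(two-sample designs). The published article prints a proportion CI
("12.96% to −26.41%") that cannot be reconstructed from its printed
quantities under either Sobel or ratio-delta constructions; this package
therefore reports its own delta-method CI and tags it as such rather than
matching an unrecoverable construction.

## Synthetic-data generator

Summary statistics are simulated directly (no individual-level genotypes):
observed betas are true betas plus N(0, se²) noise with the
standardized-trait approximation se = 1/√(2·maf·(1−maf)·n). The binary
outcome uses the effective sample size 4/(1/cases + 1/controls) for its SEs
while reporting total N, so a rare disease yields realistically wide log-OR
errors. Defaults are the motivating study's cohorts: 7,738 (exposure GWAS),
8,299 (metabolite GWAS), 500 cases / 314,193 controls (disease GWAS). Three
instrument sets of 20 variants each (counts per taxon/metabolite are not
published; 20 is typical for microbiome-taxon GWAS at p < 1×10⁻⁵) carry
point-normal effects with slab SD 0.15: exposure instruments γⱼ propagate
through the DAG (mediator effect θ_xm·γⱼ; outcome effect
(θ_direct + θ_xm·θ_my)·γⱼ + pleiotropy αⱼ), mediator-specific instruments δⱼ
affect the outcome only via θ_my, and outcome-specific instruments εⱼ feed
back on the exposure only under θ_yx ≠ 0. Pleiotropy modes: `balanced`
(mean-zero), `directional` (non-zero mean) and `inside_violating` (αⱼ
correlated 0.8 with instrument strength). LD is emitted as a pairwise r²
table with constant within-block r²; blocks sit far apart so clumping
conflicts arise only within blocks. 10% of variants get palindromic alleles.

What the generator does *not* emulate: real taxon-abundance distributions,
metabolite correlation structure, case-control ascertainment, uncertainty in
LD estimates, or population stratification. Passing tests therefore
demonstrate the statistical machinery is correct under its stated model, not
that any biological conclusion transfers to real cohorts.

## Test and simulation design sizes

Calibration checks use 500 null replicates at k = 10 with upstream GWAS of
300,000 and downstream of 50,000 — the upstream-precise regime in which the
NOME approximation underlying the ratio SEs is accurate. Parameter-recovery
checks run 20 replicates in each of the 27 cells of the
(θ_xm, θ_my, θ_direct) ∈ {−0.4, 0, 0.4}³ grid and pool coverage across the
grid. Outlier-detection checks plant a 10-standard-deviation residual in 50
seeded sets of 20 instruments.

## Numerical choices and edge cases

* p-values are clipped into (0, 1] (smallest subnormal double at the bottom)
  so downstream filters on p ∈ (0, 1] never see an exact zero.
* A single instrument delegates IVW to the Wald ratio; zero instruments raise
  a typed error. Egger/median/mode require k ≥ 3, MR-PRESSO k ≥ 4; below the
  minimum, the assembled sensitivity report leaves those fields unset instead
  of failing.
* The weighted-median interpolation clamps at the extreme ratios when the
  cumulative weight of one variant alone crosses 0.5.
* The proportion-mediated CI is reported as undefined when the total effect
  is at machine zero or the propagation overflows.
* Bootstrap redraws that land an exposure beta exactly at zero are nudged to
  the smallest positive double to keep the ratio finite.

## Known limitations

* The first-order ratio SE understates uncertainty when the exposure GWAS is
  not much more precise than the scaled outcome noise (weak instruments);
  the F ≥ 10 filter bounds but does not remove this.
* Winner's curse from selecting instruments and estimating on the same
  exposure GWAS is not corrected (the study design shares it).
* No proxy-variant substitution, multivariable MR, Steiger filtering, or
  multiple-mediator decomposition.
* The Bayesian estimator's grid integration is exact only up to grid
  resolution; extremely diffuse posteriors fall back to a widened grid with a
  logged warning.
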