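# medimr

Two-sample bidirectional Mendelian randomization (MR) with two-step mediation
analysis on GWAS summary statistics.

The package is written for epidemiologists and statistical geneticists who
want to ask: *does an exposure (say, abundance of a gut-microbiota taxon)
causally affect a disease outcome, and how much of that effect runs through an
intermediate trait (say, a plasma metabolite)?* All of it works from published
summary statistics alone — no individual-level genotypes — using genetic
variants as instrumental variables.

## What it computes

For each exposure→outcome edge, instruments are selected (association
p < 1×10⁻⁵, greedy LD clumping at r² ≤ 0.001 within 1,000 kb, per-variant
F = β²/SE² ≥ 10, optional confounder blocklist), alleles are harmonized onto a
shared effect-allele convention (palindromic A/T and C/G variants dropped by
default), and the causal effect is estimated from the per-variant Wald ratios
ρⱼ = β̂_outcome,j / β̂_exposure,j:

* **IVW** (primary): β̂ = Σwⱼρⱼ / Σwⱼ with wⱼ = 1/se(ρⱼ)²; random-effects SE
  inflation by √(Q/(k−1)) floored at 1 when Cochran's Q has p < 0.05.
* **MR-Egger**: weighted regression with intercept; the intercept estimates
  average directional pleiotropy.
* **Weighted median**, **simple mode**, and a **Bayesian weighted** estimator
  (normal pleiotropy model, dense-grid posterior).

Sensitivity analysis covers Cochran's Q, the Egger intercept test, MR-PRESSO
(global, per-variant outlier and distortion tests) and leave-one-out, plus
scatter/forest/funnel/leave-one-out plots.

Mediation uses the two-step product-of-coefficients decomposition on the
log-OR scale, guarded by reverse-MR nullity gates on every edge:

    indirect = β₁·β₂        direct = total − indirect
    proportion mediated = indirect / total

with the Sobel SE for the indirect effect and a delta-method CI for the
proportion. A negative proportion flags inconsistent mediation (the mediator
opposes the total effect — negative feedback).

A synthetic-data module generates multi-trait GWAS summary statistics under a
known exposure→mediator→outcome DAG (sampling noise, pleiotropy modes, LD
blocks, palindromic variants, reverse feedback) so the whole pipeline is
testable end to end.

## Worked example

Simulate a cohort-scale dataset with a true mediated pathway
(θ_xm = 0.3, θ_my = 0.4, θ_direct = −0.6, so the true total effect is −0.48
and the true proportion mediated −25%), then run the gated mediation:

```sh
cat > sim.yaml <<EOF
theta_xm: 0.3
theta_my: 0.4
theta_xy_direct: -0.6
gamma_sd: 0.25
EOF
medi-mr simulate --config sim.yaml --seed 3 --out demo
medi-mr mediate --exposure demo/exposure.tsv --mediator demo/mediator.tsv \
    --outcome demo/outcome.tsv --ld demo/ld.tsv --seed 17 --out demo/results
```

which prints

```
total=-0.5698 indirect=+0.1074 direct=-0.6771 proportion mediated=-18.842%
```

Reading it: the exposure lowers outcome risk overall (total log-OR −0.57,
OR ≈ 0.57), the exposure raises the mediator (β₁ = +0.31) and the mediator
raises outcome risk (β₂ = +0.35), so the indirect path (+0.11) *opposes* the
protective total effect — an inconsistent-mediation pattern, hence the
negative proportion. Estimates carry sampling noise at the default cohort
sizes (7,738 / 8,299 / 500 cases + 314,193 controls): the delta-method CI for
the proportion in this run is (−24.0%, −13.7%), narrowly missing the truth of
−25% — a reminder that with a rare-disease outcome the second-step estimate
is noisy. The test suite quantifies exactly this with coverage simulations
over a grid of true effects.

All of the above is also available as library calls
(`medimr.two_step_mediation`, `medimr.screen_exposures`, `medimr.ivw`, ...).

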