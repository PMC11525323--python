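# Methods

## The model

`sharedmap` fits joint Bayesian models for two areal count outcomes —
think offenders and offenses, or two related diseases — observed on a
partition of a study region into small areas. For area *i* and outcome
*k*, counts are Poisson,

    O_ik ~ Poisson(lambda_ik),

with expected counts E_ik (from indirect standardization) entering as a
fixed offset. Two families are provided.

**Convolution (BYM) family** — a single outcome with spatially
structured and unstructured random effects:

    log lambda_i = log E_i + b0 + X_i b + s_i + u_i,

with an intrinsic CAR (ICAR) prior on *s* and iid normal effects *u*.
The second outcome can optionally enter as a covariate through its crude
risk ratio O_i2 / E_i2, which is the classical "regress one outcome on
the other" analysis the joint family is designed to replace.

**Shared-component family** — both outcomes jointly, linked through a
common spatially structured risk field theta scaled asymmetrically:

    log lambda_i1 = log E_i1 + a1 + delta * theta_i + X_i b + s_i1 + u_i1
    log lambda_i2 = log E_i2 + a2 + (1/delta) * theta_i + X_i b + s_i2 + u_i2

The scaling parameter delta > 0 measures the relative strength of the
shared risk gradient in the two outcomes; delta near 1 means both
outcomes load on the common field with similar gradients. Each outcome
keeps its own convolution pair (s_ik, u_ik) for non-shared risk. By
default one coefficient vector b is common to both outcomes
(outcome-specific coefficients are available via
`ModelSpec(covariate_sharing="outcome_specific")`). The model prints two
intercept-like symbols for outcome 1 in its covariate-adjusted form;
their sum is unidentifiable, so a single intercept a1 is used.

### ICAR prior and identification

The ICAR prior on a structured field x is the improper Gaussian with log
density (up to a constant)

    ((n - c)/2) log tau  -  (tau/2) * sum_{i~j} (x_i - x_j)^2,

where the sum runs over neighbour pairs and c is the number of connected
components of the adjacency graph (the rank deficiency of the
Laplacian). Identification is by per-component sum-to-zero centering,
the standard choice for convolution models; a proper-CAR approximation
is deliberately not used. Isolated areas form their own component and
their structured effect is fixed at 0. Contiguity can be rook or queen
(both supported; the choice is a config field) or read from a GAL file.

### Priors

The default hyperpriors are the weakly-informative disease-mapping
standard, all overridable through `PriorConfig`:

| parameter | prior | default |
|---|---|---|
| intercepts a_k, coefficients b_j | Normal(0, sigma^2) | sigma^2 = 1000 |
| log delta | Normal(0, 0.3^2) | keeps delta positive, a priori near 1 |
| tau_theta, tau_s (ICAR precisions) | Gamma(shape, rate) | (0.5, 0.0005) |
| tau_u (iid precisions) | Gamma(shape, rate) | (0.5, 0.0005) |

## Inference

Sampling is Metropolis-within-Gibbs, matching the WinBUGS-era lineage of
these models (no gradients, every update verifiable in isolation):

1. **Latent field sites** (theta_i, s_ik, u_ik): single-site adaptive
   random-walk Metropolis, per-site proposal scales adapted toward 0.44
   acceptance (Roberts–Rosenthal increments, frozen after burn-in).
   Updates are vectorised over graph-colouring classes: sites in one
   colour class share no edge, so their full conditionals do not
   interact and a simultaneous accept/reject equals the sequential
   single-site sweep in a fixed order.
2. **Regression block** (alpha, beta): multivariate random-walk
   Metropolis with the proposal covariance estimated from the burn-in
   history (Haario-style, 2.38^2/d scaling), adapted toward 0.234
   acceptance (0.44 when the block is scalar).
3. **log delta**: scalar adaptive random-walk Metropolis.
4. **Precisions**: exact Gibbs draws from the conjugate Gamma full
   conditionals, Gamma(a + (n-c)/2, b + SS/2) for ICAR fields and
   Gamma(a + n/2, b + sum u^2/2) for iid fields.
5. **Re-centering**: after each sweep theta and s are re-centred and the
   removed mean absorbed into the intercepts (delta-weighted for theta),
   which keeps every retained state on the constraint manifold without
   changing any Poisson mean. Exactness of the absorption requires a
   connected graph, which `run_mcmc` enforces.

### Likelihood-invariant ridge moves

The posterior of these models has severe ridges: the unstructured
effects u can absorb covariate signal, asymmetric shared signal, or the
delta loading, and single-parameter moves then cannot escape (the
likelihood pins them in place). Plain Metropolis-within-Gibbs mixes
pathologically slowly along these directions — posterior means of delta
and of the shared-variance fraction from short chains can be badly wrong
while looking converged. Four deterministic-map MH moves that leave
every Poisson mean *exactly* unchanged are therefore interleaved, with
acceptance driven purely by the priors (plus a Jacobian where a scaling
is involved):

* **delta–u ridge**: shift log delta and translate u1, u2 to compensate.
* **delta–theta rescale**: scale theta by e^-eps while shifting log
  delta by eps (outcome 1 invariant), absorbing outcome 2's change into
  u2; carries the Jacobian of scaling theta on its (n - c)-dimensional
  constraint manifold.
* **shared-vs-specific transfer**: translate theta by a smooth random
  direction drawn in the scaled Laplacian eigenbasis, compensating in s1
  and s2; this is what lets the shared-variance fraction mix.
* **regression–u ridge**: shift (alpha, beta) and subtract the implied
  linear-predictor change from u1, u2.

All four were validated by comparing posterior marginals of delta and
the variance fraction against independent `rjags` fits of the identical
model (ICAR expressed exactly in the Laplacian eigenbasis) on 8x8 and
10x10 lattices: with the moves enabled the two samplers agree; without
them this sampler's chains stick in likelihood-equivalent configurations.

Initialization is deterministic: intercepts at log(sum O / sum E),
everything else at zero (precisions at 10, delta at 1). Chains use
independent streams spawned from a single seed, so every run is exactly
reproducible.

### Convergence and model comparison

`gelman_rubin` implements the classic between/within potential scale
reduction, clamped below at 1 (so identical chains report exactly 1.0)
and returning +inf when chains are constant but disagree; effective
sample sizes come from arviz. DIC uses the Poisson deviance with the
data-only log O! term omitted consistently; pD is the classic plug-in
version, with the plug-in deviance evaluated at the posterior-mean
linear predictor, and DIC can be reported per outcome ("DIC for outcome
1") or jointly — per-outcome DICs add exactly to the joint one. pD
smaller than 1e-10 relative to Dbar is snapped to zero so that
degenerate chains report pD = 0 exactly.

## Risk surfaces and hotspots

Per-area summaries across retained draws: posterior means of
exp(theta_i), exp(s_ik), exp(u_ik) or exp(s_ik + u_ik); equal-tailed
2.5%/97.5% credible intervals (the era-standard reporting convention;
HPD intervals are not used); exceedance probabilities
Pr(exp(component) > 1 | data); a significance flag (lower CI bound above
1); and hotspot classes binning the exceedance probability with
left-closed bins — minimal < 0.5 <= weak < 0.8 <= moderate < 0.9 <= strong.

The **shared-variance fraction** Var(delta*theta) / (Var(delta*theta) +
Var(s1) + Var(u1)) uses across-area empirical variances, computed per
retained draw and then summarised by the posterior mean and equal-tailed
95% CI (computing it per draw, rather than from posterior-mean fields,
is what makes an interval possible). Draws with zero total variance are
excluded with a logged count.

## Synthetic data

Real small-area crime data are typically privacy-restricted, so the
generator produces datasets with known truth that emulate the target
data structure: a nrows x ncols lattice (rook or queen) standing in for
census-area contiguity, iid standard-normal covariates (optionally
ICAR-correlated for stress tests), latent fields drawn from the exact
ICAR law restricted to the sum-to-zero subspace, and Poisson counts.
The "sd" of an ICAR field is defined on the *marginal* scale — draws are
rescaled so the average per-area marginal variance equals sd^2 — which
makes the configured sds directly comparable to the empirical-variance
fraction statistic.

Desk-scale defaults: 15x15 queen lattice (225 areas; a ~1128-area
full-scale run is `nrows=47, ncols=24`), sd_theta = 0.4, sd_s = 0.2,
sd_u = 0.1, delta in [1.0, 1.5], expected counts of 5 per area-outcome
(a realistic magnitude for two-year event tallies in 400–800-person
census areas). Problem sizes in the test suite and acceptance script
(225 areas, chains of 9000 sweeps, 8–20 replicates) were chosen as
desk-scale profiles that keep a full run in minutes.

What the generator does *not* emulate: real census-geography contiguity
(irregular polygons, islands), spatially autocorrelated covariates (by
default), population-size variation in E, or reporting artefacts. A
passing recovery study therefore shows the estimator works under the
model's own assumptions at desk scale — not that the model is correct
for any particular real dataset.

## Known limitations

* **Weak identification of the risk decomposition at low counts.** With
  ~5 expected events per area, per-area Poisson noise on the log scale
  (~0.45) exceeds the latent field scales, and the attribution of smooth
  risk between delta*theta and (s1, u1) is largely prior-driven. The
  posterior mean of the shared-variance fraction is then biased toward
  the shared component (theta is informed by both outcomes) by roughly
  +0.1–0.2 at 225 areas; independent rjags fits reproduce this, so it is
  a property of the correct posterior at this data strength, not a
  sampler artefact. Practical implication: on weak data, report the
  fraction's full CI, never just its posterior mean.
* Coverage of the 95% CI for delta at desk scale is ~85–95% against
  fixed generating values; the Normal(0, 0.3^2) prior on log delta
  shrinks estimates toward 1, which costs coverage when the true delta
  is far from 1 relative to the data strength.
* Disconnected adjacency graphs are rejected by the sampler (exact
  intercept absorption requires one component); the spatial-structure
  and simulation layers support them.
* DIC is the only comparison criterion (by design); WAIC/LOO are out of
  scope, as are zero-inflated, negative-binomial, spatio-temporal, and
  >2-outcome extensions.
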