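# sharedmap

Bayesian shared-component spatial modelling of paired areal count
outcomes: joint Poisson models in which two outcomes (e.g. young
offenders and violent offenses, or two related diseases) share a common
spatially structured risk field, fitted by MCMC, compared by DIC, and
summarised as relative-risk surfaces and exceedance-probability hotspot
maps.

## Who this is for

Spatial epidemiologists and crime analysts who want to ask "where do two
outcomes co-vary, and how strongly?" without forcing one outcome to be
the regressor of the other. Instead of a coefficient, the answer is a
map: a latent shared field with per-area exceedance probabilities, plus
a scalar that says how symmetric the association is.

## The model

For area *i* and outcome *k* in {1, 2}, counts are Poisson with
standardized expected counts as offsets:

    O_ik ~ Poisson(lambda_ik)
    log lambda_i1 = log E_i1 + a1 + delta * theta_i + X_i b + s_i1 + u_i1
    log lambda_i2 = log E_i2 + a2 + (1/delta) * theta_i + X_i b + s_i2 + u_i2

* `theta` — shared spatially structured field (intrinsic CAR prior),
  the common risk surface of both outcomes;
* `delta > 0` — scaling of the shared risk gradient: delta near 1 means
  both outcomes load on the shared field with similar gradients;
* `s_ik`, `u_ik` — outcome-specific structured (ICAR) and unstructured
  (iid normal) effects, the non-shared risk;
* `X_i b` — optional log-linear covariate effects.

Single-outcome convolution (BYM) models — with the second outcome
optionally included as a covariate via its crude risk ratio — are
provided as the non-joint baselines (models 1 and 2; the joint model
without and with covariates is models 3 and 4).

Key reported quantities: posterior summaries of `exp(theta_i)` with
`Pr(exp(theta_i) > 1 | data)` (shared hotspots), `Pr(exp(s_i1 + u_i1) >
1 | data)` (outcome-1-specific hotspots), the shared-variance fraction
`Var(delta*theta) / (Var(delta*theta) + Var(s1) + Var(u1))`, and
per-outcome DIC for model comparison.

## Worked example

Real small-area police data are privacy-restricted, so the package
ships a generator that simulates from the model with known truth
(`examples/` has one script per capability). From
`examples/02_fit_shared_component_model.py`:

```python
from sharedmap import (MCMCConfig, SimConfig, generate_dataset,
                       model_number_spec, run_mcmc, shared_variance_fraction)

sim = SimConfig(nrows=10, ncols=10, delta=1.3, seed=7)
dataset, truth = generate_dataset(sim)
samples = run_mcmc(model_number_spec(3), dataset,
                   MCMCConfig(n_chains=2, n_iter=10000, n_burnin=5000, thin=5, seed=1))
```

Output of the script:

```
delta: posterior mean 1.121, 95% CI (0.632, 1.736) [truth 1.3]
shared-variance fraction: 0.400 (0.051, 0.863) [truth 0.720]
outcome-1 DIC: -822.30 (Dbar -869.04, pD 46.74)
R-hat(delta) = 1.032  (near 1 = converged)
```

Reading: the 95% credible interval for delta covers the generating
value 1.3 and is consistent with delta = 1 (similar risk gradients); the
fraction's posterior mean understates the generating 0.72 but its 95%
interval covers it — at 100 areas with ~5 expected events each, the
split of risk between shared and specific fields is genuinely uncertain,
which is exactly why the interval, not the point estimate, should be
reported (see `docs/methods.md`). DIC omits the constant log(O!) term,
so only differences between models are meaningful. R-hat near 1
indicates the two chains agree.

A thin CLI wraps the same library calls for shell use:

```bash
sharedmap simulate --config cfg.yaml --out sim/
sharedmap fit --model 4 --data sim/data.csv --adj sim/adjacency.gal --out fit/
sharedmap summarize --fit fit/ --out results/
sharedmap recover --config cfg.yaml --seed 1 --out recovery/
```

Every output directory contains a `manifest.json` (config snapshot,
seeds, input digests); re-running with the same seed reproduces results
bit-identically.

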