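# Example configuration for the sharedmap CLI.
# Field names mirror the SimConfig / PriorConfig / MCMCConfig dataclasses.

simulate:
  nrows: 15            # lattice rows (15x15 = 225 areas, desk scale)
  ncols: 15
  rule: queen          # rook | queen contiguity
  beta: [1.2, 0.01, 0.03]   # covariate effects (empty list = no covariates)
  alpha: [0.0, 0.0]    # outcome intercepts
  delta: 1.2           # shared-risk scaling (outcome 1: delta, outcome 2: 1/delta)
  sd_theta: 0.4        # marginal sd of the shared ICAR field
  sd_s1: 0.2           # outcome-specific structured fields
  sd_s2: 0.2
  sd_u1: 0.1           # outcome-specific unstructured effects
  sd_u2: 0.1
  expected_count_base: 5.0
  seed: 42

model: 4               # 1 = BYM+covariates, 2 = BYM+covariates+outcome-2 SIR,
                       # 3 = shared no covariates, 4 = shared + covariates

priors:
  beta_prior_sd: 31.6227766016838   # Normal(0, 1000) on intercepts/coefficients
  logdelta_prior_sd: 0.3
  tau_gamma_shape: 0.5              # Gamma(shape, rate) on ICAR precisions
  tau_gamma_rate: 0.0005
  u_tau_gamma_shape: 0.5            # and on iid precisions
  u_tau_gamma_rate: 0.0005

mcmc:
  n_chains: 2
  n_iter: 9000
  n_burnin: 4000
  thin: 5
  seed: 1

recover:               # used by `sharedmap recover`
  study: recovery      # recovery | discrimination
  n_replicates: 20
  model: 3
  delta_values: [1.0, 1.3]
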