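"""Simulate a two-outcome areal dataset from the shared-component model.

Builds a 10x10 queen-contiguity lattice, draws a shared spatial risk field
theta (entering outcome 1 as delta*theta and outcome 2 as theta/delta),
outcome-specific structured and unstructured effects, and Poisson counts
around the implied means.
"""

import numpy as np

from sharedmap import SimConfig, generate_dataset, true_variance_fraction

config = SimConfig(nrows=10, ncols=10, delta=1.3, beta=[0.8], seed=42)
dataset, truth = generate_dataset(config)

print(f"areas: {dataset.n_areas}, outcomes: {dataset.n_outcomes}")
print(f"total counts: outcome 1 = {dataset.O[:, 0].sum()}, outcome 2 = {dataset.O[:, 1].sum()}")
print(f"generating delta: {truth.delta}")
print(f"sd of shared field theta: {truth.theta.std():.3f}")
print(f"true shared-variance fraction: {true_variance_fraction(truth):.3f}")
print(f"crude SIR of outcome 1, first 5 areas: "
      f"{np.round(dataset.O[:5, 0] / dataset.E[:5, 0], 2)}")

# The fraction is the share of outcome-1 log-risk variation carried by the
# common field delta*theta, relative to the specific effects s1 and u1 --
# the quantity the fitted model must recover from counts alone.
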