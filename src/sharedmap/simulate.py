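"""Forward simulation from the shared-component generative model.

Because the motivating police data are privacy-restricted, every
downstream stage is exercised on synthetic areal data with known truth.
The generator draws the latent fields of the joint model — a shared ICAR
field theta entering outcome 1 as delta*theta and outcome 2 as
(1/delta)*theta, outcome-specific ICAR fields s_k, iid heterogeneity u_k,
and log-linear covariate effects — and then Poisson counts around the
implied means.

The "sd" of an ICAR field is defined on the marginal scale: draws are
rescaled so the average per-area marginal variance equals sd^2.  That
makes the configured sds directly comparable to the empirical-variance
decomposition used by the shared-variance-fraction statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ArealDataset
from .spatial import AdjacencyGraph, build_lattice_adjacency

__all__ = ["SimConfig", "SyntheticTruth", "sample_icar", "generate_dataset", "true_variance_fraction"]


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate the desk-scale profile used throughout the test
    suite: a 15x15 queen-contiguity lattice (225 areas; the full-scale
    profile of ~1128 areas is ``nrows=47, ncols=24``), a shared field
    visibly stronger than the outcome-specific effects (sd_theta=0.4,
    sd_s=0.2, sd_u=0.1), delta near 1, and modest per-area expected
    counts as in small-area crime data.
    """

    nrows: int = 15
    ncols: int = 15
    rule: str = "queen"
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    alpha: tuple[float, float] = (0.0, 0.0)
    delta: float = 1.2
    sd_theta: float = 0.4
    sd_s1: float = 0.2
    sd_s2: float = 0.2
    sd_u1: float = 0.1
    sd_u2: float = 0.1
    expected_count_base: float | np.ndarray = 5.0
    spatial_covariates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        for name in ("sd_theta", "sd_s1", "sd_s2", "sd_u1", "sd_u2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if np.any(np.asarray(self.expected_count_base, dtype=float) <= 0):
            raise ValueError("expected_count_base must be positive")

    @property
    def n_covariates(self) -> int:
        return self.beta.shape[0]


@dataclass
class SyntheticTruth:
    """Generating parameter values paired with the realized Poisson means."""

    theta: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    u1: np.ndarray
    u2: np.ndarray
    delta: float
    alpha: tuple[float, float]
    beta: np.ndarray
    lam: np.ndarray  # (n_areas, 2)


def _icar_factor(graph: AdjacencyGraph) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of the Laplacian restricted to nonzero eigenvalues."""
    lap = graph.laplacian()
    evals, evecs = np.linalg.eigh(lap)
    keep = evals > 1e-9 * max(evals.max(), 1.0)
    return evals[keep], evecs[:, keep]


def sample_icar(graph: AdjacencyGraph, sd: float, rng: np.random.Generator) -> np.ndarray:
    """One draw of a zero-mean ICAR field with average marginal variance sd^2.

    The field lives in the per-component sum-to-zero subspace: with
    Laplacian eigenpairs (l_j, v_j), x = sum_j z_j v_j / sqrt(l_j) over the
    nonzero eigenvalues, rescaled so mean_i Var(x_i) = sd^2.  Isolated
    areas (singleton components) get exactly 0.  sd=0 returns zeros.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    n = graph.n_areas
    if sd == 0:
        return np.zeros(n)
    evals, evecs = _icar_factor(graph)
    if evals.size == 0:
        return np.zeros(n)
    z = rng.standard_normal(evals.size)
    x = evecs @ (z / np.sqrt(evals))
    # average marginal variance of the unscaled field = trace(L^+)/n
    avg_var = float(np.sum(1.0 / evals)) / n
    return x * (sd / np.sqrt(avg_var))


def generate_dataset(config: SimConfig) -> tuple[ArealDataset, SyntheticTruth]:
    """Simulate one areal dataset plus the truth that generated it.

    Covariates are iid standard normal by default (``spatial_covariates``
    draws them as unit-scale ICAR fields instead, as a stress test);
    both outcomes share the same covariate effects, matching the joint
    model with a single coefficient vector.
    """
    graph = build_lattice_adjacency(config.nrows, config.ncols, config.rule)
    n = graph.n_areas
    rng = np.random.default_rng(config.seed)
    p = config.n_covariates
    if config.spatial_covariates and p:
        X = np.column_stack([sample_icar(graph, 1.0, rng) for _ in range(p)])
    else:
        X = rng.standard_normal((n, p))
    theta = sample_icar(graph, config.sd_theta, rng)
    s1 = sample_icar(graph, config.sd_s1, rng)
    s2 = sample_icar(graph, config.sd_s2, rng)
    u1 = config.sd_u1 * rng.standard_normal(n)
    u2 = config.sd_u2 * rng.standard_normal(n)
    E = np.broadcast_to(
        np.asarray(config.expected_count_base, dtype=float).reshape(-1, 1), (n, 2)
    ).copy() if np.ndim(config.expected_count_base) else np.full((n, 2), float(config.expected_count_base))
    xb = X @ config.beta if p else np.zeros(n)
    log_lam1 = np.log(E[:, 0]) + config.alpha[0] + config.delta * theta + xb + s1 + u1
    log_lam2 = np.log(E[:, 1]) + config.alpha[1] + theta / config.delta + xb + s2 + u2
    log_lam = np.column_stack([log_lam1, log_lam2])
    if np.any(np.abs(log_lam) > 50):
        raise ValueError(
            "linear predictor exceeds +-50 (exp overflow); use smaller field sds or effects"
        )
    lam = np.exp(log_lam)
    O = rng.poisson(lam)
    dataset = ArealDataset(graph, O, E, X, [f"x{j + 1}" for j in range(p)])
    truth = SyntheticTruth(theta, s1, s2, u1, u2, config.delta, config.alpha, config.beta.copy(), lam)
    return dataset, truth


def true_variance_fraction(truth: SyntheticTruth) -> float:
    """Fraction of outcome-1 log-risk variation carried by the shared field.

    Var(delta*theta) / (Var(delta*theta) + Var(s1) + Var(u1)), with
    empirical (across-area, population) variances of the true latent
    vectors.  The posterior analogue is computed per MCMC draw by the
    risk-mapping module.
    """
    v_shared = float(np.var(truth.delta * truth.theta))
    v_s = float(np.var(truth.s1))
    v_u = float(np.var(truth.u1))
    denom = v_shared + v_s + v_u
    if denom == 0:
        raise ValueError("all variance components are zero; fraction undefined")
    return v_shared / denom
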