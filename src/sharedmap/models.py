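"""Model structures, priors, and log-posterior evaluation.

Two model families for areal Poisson counts:

* ``bym`` — the Besag convolution model for a single outcome,
  ``log lambda_i = log E_i + b0 + X_i b + s_i + u_i``, with an ICAR prior on
  the structured effect s and iid normal on u.  With the second outcome's
  crude risk ratio appended as a covariate this is the classical
  "one outcome regressed on the other" analysis.

* ``shared`` — the joint shared-component model for two outcomes.  A single
  spatially structured field theta is shared between outcomes, entering
  outcome 1 scaled by delta and outcome 2 by 1/delta:

      log lambda_i1 = log E_i1 + a1 + delta*theta_i + X_i b + s_i1 + u_i1
      log lambda_i2 = log E_i2 + a2 + (1/delta)*theta_i + X_i b + s_i2 + u_i2

  delta > 0 measures the relative contribution of the two outcomes to the
  shared risk gradient (delta near 1: similar gradients).  Each outcome
  keeps its own convolution pair (s_ik, u_ik) for non-shared risk.

Priors: normal on intercepts/coefficients, normal on log delta, gamma on
all precision parameters, ICAR on structured fields.  All constants are
configurable through :class:`PriorConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma

import numpy as np

from .data import ArealDataset, crude_sir
from .spatial import AdjacencyGraph, check_centered, icar_logdensity

__all__ = [
    "PriorConfig",
    "ModelSpec",
    "ParamState",
    "model_number_spec",
    "effective_design",
    "linear_predictor",
    "poisson_loglik",
    "log_posterior",
]


@dataclass
class PriorConfig:
    """Hyperparameters of all prior distributions.

    Defaults are the weakly-informative choices standard in disease
    mapping: variance-1000 normals on regression terms, Gamma(0.5, 0.0005)
    on precisions, and a log-normal on delta keeping it positive and a
    priori near 1.
    """

    beta_prior_sd: float = 31.6227766016838  # sqrt(1000)
    logdelta_prior_sd: float = 0.3
    tau_gamma_shape: float = 0.5
    tau_gamma_rate: float = 0.0005
    u_tau_gamma_shape: float = 0.5
    u_tau_gamma_rate: float = 0.0005

    def __post_init__(self) -> None:
        for name in (
            "beta_prior_sd",
            "logdelta_prior_sd",
            "tau_gamma_shape",
            "tau_gamma_rate",
            "u_tau_gamma_shape",
            "u_tau_gamma_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ModelSpec:
    """Which model structure to fit.

    ``family='bym'`` is the single-outcome convolution model;
    ``family='shared'`` the two-outcome shared-component model.
    ``include_outcome2_as_covariate`` (bym only) appends the crude SIR of
    outcome 2 as an extra covariate.  ``covariate_sharing`` controls
    whether the shared family uses one coefficient vector for both
    outcomes (default) or outcome-specific vectors.
    """

    family: str = "shared"
    include_covariates: bool = True
    include_outcome2_as_covariate: bool = False
    covariate_sharing: str = "shared"
    priors: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        if self.family not in ("bym", "shared"):
            raise ValueError(f"family must be 'bym' or 'shared', got {self.family!r}")
        if self.covariate_sharing not in ("shared", "outcome_specific"):
            raise ValueError("covariate_sharing must be 'shared' or 'outcome_specific'")
        if self.include_outcome2_as_covariate and self.family != "bym":
            raise ValueError("include_outcome2_as_covariate is only valid for the bym family")

    @property
    def n_outcomes(self) -> int:
        return 2 if self.family == "shared" else 1


def model_number_spec(model: int, priors: PriorConfig | None = None) -> ModelSpec:
    """The four numbered analysis models.

    1: bym, covariates only; 2: bym, covariates + outcome-2 risk ratio as a
    covariate; 3: shared, no covariates; 4: shared, covariates (one
    coefficient vector for both outcomes).
    """
    priors = priors or PriorConfig()
    table = {
        1: ModelSpec("bym", True, False, priors=priors),
        2: ModelSpec("bym", True, True, priors=priors),
        3: ModelSpec("shared", False, False, priors=priors),
        4: ModelSpec("shared", True, False, priors=priors),
    }
    if model not in table:
        raise ValueError(f"model must be 1..4, got {model}")
    return table[model]


def effective_design(spec: ModelSpec, data: ArealDataset) -> tuple[np.ndarray, list[str]]:
    """The covariate matrix the model actually uses.

    Empty when include_covariates is false; for bym with
    include_outcome2_as_covariate the crude SIR of outcome 2 is appended
    (mean-centred like the other covariates are expected to be).
    """
    if not spec.include_covariates and not spec.include_outcome2_as_covariate:
        return np.empty((data.n_areas, 0)), []
    X = data.X if spec.include_covariates else np.empty((data.n_areas, 0))
    names = list(data.covariate_names) if spec.include_covariates else []
    if spec.include_outcome2_as_covariate:
        if data.n_outcomes < 2:
            raise ValueError("outcome 2 covariate requested but dataset has one outcome")
        sir2 = crude_sir(data.O[:, 1], data.E[:, 1])
        X = np.column_stack([X, sir2 - sir2.mean()])
        names = names + ["sir_k2"]
    return X, names


@dataclass
class ParamState:
    """One complete set of model unknowns.

    Shapes: ``alpha`` (n_outcomes,); ``beta`` (p,) when coefficients are
    shared across outcomes, (p, 2) when outcome-specific; ``theta`` (n,)
    (shared family only, per-component centred); ``s`` list of centred
    (n,) vectors, one per outcome; ``u`` list of (n,) vectors; precisions
    are scalars (tau_s, tau_u per outcome).
    """

    alpha: np.ndarray
    beta: np.ndarray
    theta: np.ndarray | None
    s: list[np.ndarray]
    u: list[np.ndarray]
    delta: float
    tau_theta: float
    tau_s: list[float]
    tau_u: list[float]

    def copy(self) -> "ParamState":
        return ParamState(
            alpha=self.alpha.copy(),
            beta=self.beta.copy(),
            theta=None if self.theta is None else self.theta.copy(),
            s=[v.copy() for v in self.s],
            u=[v.copy() for v in self.u],
            delta=self.delta,
            tau_theta=self.tau_theta,
            tau_s=list(self.tau_s),
            tau_u=list(self.tau_u),
        )

    def validate(self, spec: ModelSpec, graph: AdjacencyGraph) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.tau_theta <= 0 or any(t <= 0 for t in self.tau_s) or any(
            t <= 0 for t in self.tau_u
        ):
            raise ValueError("precision parameters must be positive")
        if spec.family == "shared":
            if self.theta is None:
                raise ValueError("shared family requires theta")
            if not check_centered(self.theta, graph):
                raise ValueError("theta violates the per-component sum-to-zero constraint")
        for sv in self.s:
            if not check_centered(sv, graph):
                raise ValueError("s violates the per-component sum-to-zero constraint")


def _beta_for_outcome(spec: ModelSpec, state: ParamState, k: int) -> np.ndarray:
    if state.beta.ndim == 2:
        return state.beta[:, k]
    return state.beta


def log_linear_predictor(
    spec: ModelSpec, state: ParamState, data: ArealDataset, k: int
) -> np.ndarray:
    """log lambda_k including the log E offset (outcome k is 1-based)."""
    if k not in range(1, spec.n_outcomes + 1):
        raise ValueError(f"outcome index {k} invalid for family {spec.family!r}")
    ki = k - 1
    X, _ = effective_design(spec, data)
    eta = np.log(data.E[:, ki]) + state.alpha[ki]
    if X.shape[1]:
        b = _beta_for_outcome(spec, state, ki)
        if X.shape[1] != b.shape[0]:
            raise ValueError(f"design has {X.shape[1]} columns but beta has {b.shape[0]}")
        eta = eta + X @ b
    if spec.family == "shared":
        load = state.delta if k == 1 else 1.0 / state.delta
        eta = eta + load * state.theta
    eta = eta + state.s[ki] + state.u[ki]
    return eta


def linear_predictor(spec: ModelSpec, state: ParamState, data: ArealDataset, k: int) -> np.ndarray:
    """Poisson mean vector lambda_k = exp(offset + linear predictor)."""
    return np.exp(log_linear_predictor(spec, state, data, k))


def poisson_loglik(O: np.ndarray, lam: np.ndarray) -> float:
    """Full Poisson log likelihood sum_i [O_i log lam_i - lam_i - log O_i!]."""
    O = np.asarray(O, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if O.shape != lam.shape:
        raise ValueError("O and lam must have the same shape")
    if np.any(O < 0):
        raise ValueError("counts must be non-negative")
    if np.any(lam <= 0):
        raise ValueError("lam must be strictly positive")
    lfact = np.array([lgamma(o + 1.0) for o in np.ravel(O)]).reshape(O.shape)
    return float(np.sum(O * np.log(lam) - lam - lfact))


def _normal_logkernel(x: np.ndarray | float, sd: float) -> float:
    return float(-0.5 * np.sum(np.square(np.asarray(x, dtype=float))) / sd**2)


def _gamma_logkernel(tau: float, shape: float, rate: float) -> float:
    return (shape - 1.0) * np.log(tau) - rate * tau


def _iid_normal_logdensity(u: np.ndarray, tau: float) -> float:
    n = u.shape[0]
    return float(0.5 * n * np.log(tau) - 0.5 * tau * np.sum(u * u))


def log_posterior(spec: ModelSpec, state: ParamState, data: ArealDataset) -> float:
    """Joint log posterior up to a state-independent constant.

    Sum of the Poisson log likelihoods over outcomes, ICAR log densities on
    theta and each s_k, iid normal log densities on each u_k, normal priors
    on alpha/beta, a normal prior on log delta (delta is sampled on the log
    scale; the log-Jacobian is absorbed into that parameterisation), and
    gamma priors on every precision.
    """
    state.validate(spec, data.graph)
    pr = spec.priors
    total = 0.0
    for k in range(1, spec.n_outcomes + 1):
        lam = linear_predictor(spec, state, data, k)
        total += poisson_loglik(data.O[:, k - 1], lam)
    if spec.family == "shared":
        total += icar_logdensity(state.theta, data.graph, state.tau_theta)
        total += _normal_logkernel(np.log(state.delta), pr.logdelta_prior_sd)
    for sv, tau in zip(state.s, state.tau_s):
        total += icar_logdensity(sv, data.graph, tau)
    for uv, tau in zip(state.u, state.tau_u):
        total += _iid_normal_logdensity(uv, tau)
    total += _normal_logkernel(state.alpha[: spec.n_outcomes], pr.beta_prior_sd)
    total += _normal_logkernel(state.beta, pr.beta_prior_sd)
    total += _gamma_logkernel(state.tau_theta, pr.tau_gamma_shape, pr.tau_gamma_rate)
    for tau in state.tau_s:
        total += _gamma_logkernel(tau, pr.tau_gamma_shape, pr.tau_gamma_rate)
    for tau in state.tau_u:
        total += _gamma_logkernel(tau, pr.u_tau_gamma_shape, pr.u_tau_gamma_rate)
    return float(total)


def initial_state(spec: ModelSpec, data: ArealDataset) -> ParamState:
    """Deterministic in-support start: intercepts at log(sum O / sum E),
    coefficients and latent fields at zero, precisions at 10, delta at 1."""
    n = data.n_areas
    K = spec.n_outcomes
    X, _ = effective_design(spec, data)
    p = X.shape[1]
    alpha = np.zeros(K)
    for k in range(K):
        tot_O = data.O[:, k].sum()
        alpha[k] = np.log(max(tot_O, 0.5) / data.E[:, k].sum())
    if spec.family == "shared" and spec.covariate_sharing == "outcome_specific":
        beta = np.zeros((p, 2))
    else:
        beta = np.zeros(p)
    return ParamState(
        alpha=alpha,
        beta=beta,
        theta=np.zeros(n) if spec.family == "shared" else None,
        s=[np.zeros(n) for _ in range(K)],
        u=[np.zeros(n) for _ in range(K)],
        delta=1.0,
        tau_theta=10.0,
        tau_s=[10.0] * K,
        tau_u=[10.0] * K,
    )
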