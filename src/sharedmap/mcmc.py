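"""Metropolis-within-Gibbs posterior sampling, diagnostics, and DIC.

The sweep mirrors the WinBUGS-era samplers used for convolution and
shared-component disease-mapping models:

(a) single-site adaptive random-walk Metropolis for every latent field
    site (theta_i, s_ik, u_ik), with per-site proposal scales adapted
    toward a target acceptance rate and frozen after burn-in;
(b) block random-walk Metropolis for the regression terms (alpha, beta),
    with the proposal covariance adapted from the burn-in history;
(c) random-walk Metropolis on log delta;
(d) exact Gibbs draws for the precision parameters, whose full
    conditionals are Gamma by conjugacy:
    tau_field ~ Gamma(a + (n - c)/2, b + SS/2) for ICAR fields and
    tau_u ~ Gamma(a + n/2, b + sum u^2 / 2) for iid fields;
(e) per-sweep re-centering of theta and s with the removed mean absorbed
    into the intercepts, which keeps every retained state on the
    sum-to-zero constraint manifold without changing any Poisson mean.

Single-site updates of ICAR fields are vectorised over graph-colouring
classes: sites within a colour class share no edge, so their full
conditionals do not interact and a simultaneous accept/reject over the
class is exactly the sequential single-site sampler (in a fixed order).

Step (e) is exact only when the adjacency graph is connected (one
intercept cannot absorb distinct per-component means), so ``run_mcmc``
requires a connected graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import ArealDataset
from .models import (
    ModelSpec,
    effective_design,
    initial_state,
    log_linear_predictor,
)
from .spatial import greedy_coloring

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "ChainDiagnostics",
    "run_mcmc",
    "gelman_rubin",
    "compute_dic",
    "diagnostics",
]

log = logging.getLogger(__name__)

try:  # optional acceleration of the single-site sweep
    from numba import njit

    @njit(cache=True)
    def _site_update_kernel(
        x, eta, O, dx, unif, sites, indptr, indices, deg, tau, loadings,
        icar_prior, use_likelihood, accept_out,
    ):  # pragma: no cover - exercised via _site_update
        K = loadings.shape[0]
        for t in range(sites.shape[0]):
            i = sites[t]
            xo = x[i]
            xn = xo + dx[t]
            if icar_prior:
                s = 0.0
                for p in range(indptr[i], indptr[i + 1]):
                    s += x[indices[p]]
                dprior = -0.5 * tau * (deg[i] * (xn * xn - xo * xo) - 2.0 * dx[t] * s)
            else:
                dprior = -0.5 * tau * (xn * xn - xo * xo)
            dll = 0.0
            if use_likelihood:
                for k in range(K):
                    c = loadings[k]
                    if c != 0.0:
                        e = eta[i, k]
                        dll += O[i, k] * c * dx[t] - (np.exp(e + c * dx[t]) - np.exp(e))
            if np.log(unif[t]) < dprior + dll:
                x[i] = xn
                for k in range(K):
                    c = loadings[k]
                    if c != 0.0:
                        eta[i, k] += c * dx[t]
                accept_out[t] = 1.0
            else:
                accept_out[t] = 0.0

    @njit(cache=True)
    def _edge_ss(x, eu, ev):  # pragma: no cover - exercised via the sampler
        total = 0.0
        for t in range(eu.shape[0]):
            d = x[eu[t]] - x[ev[t]]
            total += d * d
        return total

    @njit(cache=True)
    def _edge_ss_shift(x, w, eu, ev):  # pragma: no cover
        total = 0.0
        for t in range(eu.shape[0]):
            dx = x[eu[t]] - x[ev[t]]
            dw = w[eu[t]] - w[ev[t]]
            total += dw * dw + 2.0 * dw * dx
        return total

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass
class MCMCConfig:
    """Run-length and tuning settings for the sampler.

    ``n_iter`` counts total sweeps per chain; the first ``n_burnin`` are
    discarded and the rest kept every ``thin`` sweeps.  The ``update_*``
    flags freeze parts of the state (used for conjugacy/quadrature
    checks); ``use_likelihood=False`` samples from the prior alone.
    """

    n_chains: int = 2
    n_iter: int = 20000
    n_burnin: int = 10000
    thin: int = 10
    seed: int = 0
    adapt_window: int = 50
    target_accept: float = 0.44
    block_target_accept: float = 0.234
    update_fields: bool = True
    update_only: tuple[str, ...] | None = None
    update_regression: bool = True
    update_delta: bool = True
    update_precisions: bool = True
    use_likelihood: bool = True

    def __post_init__(self) -> None:
        if not (self.n_iter > self.n_burnin >= 0):
            raise ValueError("need n_iter > n_burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.n_burnin + self.thin - 1) // self.thin


@dataclass
class PosteriorSamples:
    """Retained MCMC draws across chains.

    ``chains[c]`` maps a parameter name to an array whose first axis is
    the retained draw: scalar parameters (delta, tau_*) have shape (m,),
    vector fields (theta, s1, u1, ...) shape (m, n), alpha (m, K), beta
    (m, p) or (m, p, 2), and ``loglam`` (m, n, K) holds the log Poisson
    means for DIC computation.
    """

    spec: ModelSpec
    config: MCMCConfig
    chains: list[dict[str, np.ndarray]]
    acceptance: list[dict[str, float]]
    area_ids: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_draws(self) -> int:
        return sum(c["delta" if "delta" in c else "alpha"].shape[0] for c in self.chains)

    def parameter_names(self) -> list[str]:
        return sorted(self.chains[0].keys())

    def stacked(self, name: str) -> np.ndarray:
        """All retained draws of one parameter, chains concatenated."""
        if name not in self.chains[0]:
            raise KeyError(f"no parameter {name!r}; have {self.parameter_names()}")
        return np.concatenate([c[name] for c in self.chains], axis=0)


@dataclass
class ChainDiagnostics:
    """Convergence summary: per-scalar R-hat and ESS, per-block acceptance."""

    rhat: dict[str, float]
    ess: dict[str, float]
    acceptance: list[dict[str, float]]


# --------------------------------------------------------------------------
# sampler internals


class _Sampler:
    def __init__(self, spec: ModelSpec, data: ArealDataset, config: MCMCConfig,
                 rng: np.random.Generator) -> None:
        graph = data.graph
        if config.update_fields and graph.n_components != 1:
            raise ValueError(
                "run_mcmc requires a connected adjacency graph: per-sweep re-centering "
                "absorbs the field mean into a single intercept, which is exact only "
                f"for one component (graph has {graph.n_components})"
            )
        self.spec = spec
        self.data = data
        self.cfg = config
        self.rng = rng
        self.n = graph.n_areas
        self.K = spec.n_outcomes
        self.X, _ = effective_design(spec, data)
        self.p = self.X.shape[1]
        self.logE = np.log(data.E[:, : self.K])
        self.O = data.O[:, : self.K].astype(float)
        self.A = graph.adjacency_matrix()
        self.deg = graph.degrees.astype(float)
        self.colors = greedy_coloring(graph)
        # pre-sliced adjacency rows per colour class (hot path of the sweep)
        self.color_rows = {id(c): self.A[c] for c in self.colors}
        self.edges = graph.edges
        self.eu = np.ascontiguousarray(self.edges[:, 0]) if self.edges.size else np.zeros(0, np.int64)
        self.ev = np.ascontiguousarray(self.edges[:, 1]) if self.edges.size else np.zeros(0, np.int64)
        self.rank = self.n - graph.n_components  # ICAR rank

        self.state = initial_state(spec, data)
        self.eta = self._full_eta()

        # scaled Laplacian eigenbasis for smooth translation directions used
        # by the shared-vs-specific transfer move (shared family only)
        self._icar_basis: np.ndarray | None = None
        if spec.family == "shared" and config.update_fields:
            lap = graph.laplacian()
            evals, evecs = np.linalg.eigh(lap)
            keep = evals > 1e-9 * max(float(evals.max()), 1.0)
            if keep.any():
                self._icar_basis = evecs[:, keep] / np.sqrt(evals[keep])

        # adaptation state: per-site log proposal scales and window counters
        self.field_names = (["theta"] if spec.family == "shared" else []) + [
            f"s{k + 1}" for k in range(self.K)
        ] + [f"u{k + 1}" for k in range(self.K)]
        self.ls = {f: np.full(self.n, np.log(0.3)) for f in self.field_names}
        self.scales = {f: np.exp(v) for f, v in self.ls.items()}
        self.acc = {f: np.zeros(self.n) for f in self.field_names}
        self.all_sites = np.arange(self.n, dtype=np.int64)
        self.ls_delta = np.log(0.1)
        self.acc_delta = 0.0
        self.ls_ridge = np.log(0.1)
        self.acc_ridge = 0.0
        self.ls_transfer = np.log(0.1)
        self.acc_transfer = 0.0
        self.ls_rescale = np.log(0.1)
        self.acc_rescale = 0.0
        self.ls_block = 0.0
        self.acc_block = 0.0
        self.ls_bridge = 0.0
        self.acc_bridge = 0.0
        self.n_acc_total: dict[str, float] = {f: 0.0 for f in self.field_names}
        self.n_acc_total["delta"] = 0.0
        self.n_acc_total["delta_ridge"] = 0.0
        self.n_acc_total["transfer"] = 0.0
        self.n_acc_total["rescale"] = 0.0
        self.n_acc_total["block"] = 0.0
        self.n_acc_total["block_ridge"] = 0.0
        self.batch = 0
        # block-proposal covariance accumulators (Welford over burn-in)
        d = self._block_dim()
        self.bw_count = 0
        self.bw_mean = np.zeros(d)
        self.bw_m2 = np.zeros((d, d))
        self.block_chol: np.ndarray | None = None

    # -- linear predictor bookkeeping ----------------------------------

    def _full_eta(self) -> np.ndarray:
        return np.column_stack(
            [log_linear_predictor(self.spec, self.state, self.data, k + 1) for k in range(self.K)]
        )

    def _theta_loadings(self) -> np.ndarray:
        if self.spec.family != "shared":
            return np.zeros(self.K)
        return np.array([self.state.delta, 1.0 / self.state.delta])

    # -- generic site-level Metropolis over one colour class -----------

    def _site_update(self, name: str, x: np.ndarray, loadings: np.ndarray,
                     prior: str, tau: float, sites: np.ndarray) -> None:
        dx = self.scales[name][sites] * self.rng.standard_normal(sites.size)
        unif = self.rng.random(sites.size)
        if _HAVE_NUMBA:
            accept = np.empty(sites.size)
            _site_update_kernel(
                x, self.eta, self.O, dx, unif, sites,
                self.A.indptr, self.A.indices, self.deg, float(tau),
                loadings, prior == "icar",
                self.cfg.use_likelihood, accept,
            )
            self.acc[name][sites] += accept
            self.n_acc_total[name] += float(accept.sum())
            return
        xo = x[sites]
        xn = xo + dx
        if prior == "icar":
            rows = self.color_rows.get(id(sites))
            nb_sum = (rows if rows is not None else self.A[sites]) @ x
            dprior = -0.5 * tau * (self.deg[sites] * (xn**2 - xo**2) - 2.0 * dx * nb_sum)
        else:  # iid normal
            dprior = -0.5 * tau * (xn**2 - xo**2)
        dll = np.zeros(sites.size)
        if self.cfg.use_likelihood:
            for k, c in enumerate(loadings):
                if c == 0.0:
                    continue
                eta_o = self.eta[sites, k]
                dll += self.O[sites, k] * c * dx - (np.exp(eta_o + c * dx) - np.exp(eta_o))
        accept = np.log(unif) < dprior + dll
        if np.any(accept):
            idx = sites[accept]
            x[idx] += dx[accept]
            for k, c in enumerate(loadings):
                if c != 0.0:
                    self.eta[idx, k] += c * dx[accept]
        self.acc[name][sites] += accept
        self.n_acc_total[name] += float(accept.sum())

    def _update_field(self, name: str, x: np.ndarray, loadings: Sequence[float],
                      prior: str, tau: float) -> None:
        loadings = np.asarray(loadings, dtype=float)
        if _HAVE_NUMBA or prior != "icar":
            # sequential in-place kernel: a plain single-site sweep in site
            # order, no colouring needed
            self._site_update(name, x, loadings, prior, tau, self.all_sites)
        else:
            # vectorised numpy fallback: simultaneous updates are only exact
            # within a colour class (no intra-class edges)
            for sites in self.colors:
                self._site_update(name, x, loadings, prior, tau, sites)

    def _update_fields(self) -> None:
        st = self.state
        only = self.cfg.update_only

        def wanted(name: str) -> bool:
            return only is None or name in only

        if self.spec.family == "shared" and wanted("theta"):
            self._update_field("theta", st.theta, self._theta_loadings(), "icar", st.tau_theta)
        for k in range(self.K):
            load = [0.0] * self.K
            load[k] = 1.0
            if wanted(f"s{k + 1}"):
                self._update_field(f"s{k + 1}", st.s[k], load, "icar", st.tau_s[k])
            if wanted(f"u{k + 1}"):
                self._update_field(f"u{k + 1}", st.u[k], load, "iid", st.tau_u[k])

    # -- regression block ----------------------------------------------

    def _block_dim(self) -> int:
        return self.K + int(np.prod(self.state.beta.shape))

    def _block_get(self) -> np.ndarray:
        return np.concatenate([self.state.alpha, np.ravel(self.state.beta)])

    def _block_set(self, z: np.ndarray) -> None:
        self.state.alpha = z[: self.K].copy()
        self.state.beta = z[self.K:].reshape(self.state.beta.shape).copy()

    def _block_eta_shift(self, dz: np.ndarray) -> np.ndarray:
        """Change in eta (n, K) implied by a move dz of (alpha, beta)."""
        shift = np.empty((self.n, self.K))
        shift[:] = dz[: self.K]
        if self.p:
            dbeta = dz[self.K:].reshape(self.state.beta.shape)
            if dbeta.ndim == 2:
                shift += self.X @ dbeta
            else:
                shift += (self.X @ dbeta)[:, None]
        return shift

    def _update_block(self) -> None:
        d = self._block_dim()
        if d == 0:
            return
        if self.block_chol is not None:
            step = self.block_chol @ self.rng.standard_normal(d)
        else:
            step = 0.1 / np.sqrt(d) * self.rng.standard_normal(d)
        dz = np.exp(self.ls_block) * step
        shift = self._block_eta_shift(dz)
        dll = 0.0
        if self.cfg.use_likelihood:
            dll = float(np.sum(self.O * shift) - np.sum(np.exp(self.eta + shift) - np.exp(self.eta)))
        z = self._block_get()
        sd = self.spec.priors.beta_prior_sd
        dprior = float(-0.5 * (np.sum((z + dz) ** 2) - np.sum(z**2)) / sd**2)
        if np.log(self.rng.random()) < dll + dprior:
            self._block_set(z + dz)
            self.eta += shift
            self.acc_block += 1
            self.n_acc_total["block"] += 1

    def _update_block_ridge(self) -> None:
        """Joint move trading the regression terms against the u fields.

        Proposes a shift dz of (alpha, beta) and subtracts the implied
        linear-predictor change from each u_k, leaving every Poisson mean
        exactly unchanged; acceptance is driven by the u priors and the
        normal prior on (alpha, beta).  Without it the unstructured
        effects absorb covariate signal early in the run and the
        coefficients cannot reclaim it (the likelihood pins them).
        """
        d = self._block_dim()
        if d == 0:
            return
        if self.block_chol is not None:
            step = self.block_chol @ self.rng.standard_normal(d)
        else:
            step = 0.1 / np.sqrt(d) * self.rng.standard_normal(d)
        dz = np.exp(self.ls_bridge) * step
        shift = self._block_eta_shift(dz)
        st = self.state
        dprior = 0.0
        for k in range(self.K):
            un = st.u[k] - shift[:, k]
            dprior += -0.5 * st.tau_u[k] * float(un @ un - st.u[k] @ st.u[k])
        z = self._block_get()
        sd = self.spec.priors.beta_prior_sd
        dprior += float(-0.5 * (np.sum((z + dz) ** 2) - np.sum(z**2)) / sd**2)
        if np.log(self.rng.random()) < dprior:
            self._block_set(z + dz)
            for k in range(self.K):
                st.u[k] = st.u[k] - shift[:, k]
            self.acc_bridge += 1
            self.n_acc_total["block_ridge"] += 1

    def _accumulate_block_cov(self) -> None:
        z = self._block_get()
        self.bw_count += 1
        delta = z - self.bw_mean
        self.bw_mean += delta / self.bw_count
        self.bw_m2 += np.outer(delta, z - self.bw_mean)

    def _refresh_block_chol(self) -> None:
        d = self._block_dim()
        if d == 0 or self.bw_count < max(10 * d, 50):
            return
        cov = self.bw_m2 / (self.bw_count - 1)
        cov = 2.38**2 / d * cov + 1e-8 * np.eye(d)
        try:
            self.block_chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            pass

    # -- delta ----------------------------------------------------------

    def _update_delta(self) -> None:
        st = self.state
        ld = np.log(st.delta)
        ld_new = ld + np.exp(self.ls_delta) * self.rng.standard_normal()
        d_new = np.exp(ld_new)
        shift = np.column_stack(
            [(d_new - st.delta) * st.theta, (1.0 / d_new - 1.0 / st.delta) * st.theta]
        )
        dll = 0.0
        if self.cfg.use_likelihood:
            dll = float(np.sum(self.O * shift) - np.sum(np.exp(self.eta + shift) - np.exp(self.eta)))
        sd = self.spec.priors.logdelta_prior_sd
        dprior = -0.5 * (ld_new**2 - ld**2) / sd**2
        if np.log(self.rng.random()) < dll + dprior:
            st.delta = float(d_new)
            self.eta += shift
            self.acc_delta += 1
            self.n_acc_total["delta"] += 1

    def _update_delta_ridge(self) -> None:
        """Joint move along the likelihood ridge coupling delta and the u fields.

        Proposes log delta' = log delta + eps and shifts u1, u2 so that both
        linear predictors are exactly unchanged:

            u_k' = u_k - (load_k(delta') - load_k(delta)) * theta.

        The likelihood cancels; acceptance is driven by the iid-normal
        priors on u and the log-delta prior (the u-translation has unit
        Jacobian).  Without this move the single-parameter delta update
        mixes very slowly whenever the unstructured effects have absorbed
        part of the shared signal.
        """
        st = self.state
        ld = np.log(st.delta)
        ld_new = ld + np.exp(self.ls_ridge) * self.rng.standard_normal()
        d_new = np.exp(ld_new)
        du1 = -(d_new - st.delta) * st.theta
        du2 = -(1.0 / d_new - 1.0 / st.delta) * st.theta
        u1n = st.u[0] + du1
        u2n = st.u[1] + du2
        dprior = (
            -0.5 * st.tau_u[0] * float(u1n @ u1n - st.u[0] @ st.u[0])
            - 0.5 * st.tau_u[1] * float(u2n @ u2n - st.u[1] @ st.u[1])
            - 0.5 * (ld_new**2 - ld**2) / self.spec.priors.logdelta_prior_sd**2
        )
        if np.log(self.rng.random()) < dprior:
            st.delta = float(d_new)
            st.u[0] = u1n
            st.u[1] = u2n
            # eta is unchanged by construction
            self.acc_ridge += 1
            self.n_acc_total["delta_ridge"] += 1

    def _delta_ss_after_shift(self, x: np.ndarray, w: np.ndarray) -> float:
        """Change in the ICAR pairwise sum of squares when x becomes x + w."""
        e = self.edges
        if e.size == 0:
            return 0.0
        if _HAVE_NUMBA:
            return float(_edge_ss_shift(x, w, self.eu, self.ev))
        dx = x[e[:, 0]] - x[e[:, 1]]
        dw = w[e[:, 0]] - w[e[:, 1]]
        return float(dw @ dw + 2.0 * (dw @ dx))

    def _edge_sumsq(self, x: np.ndarray) -> float:
        e = self.edges
        if e.size == 0:
            return 0.0
        if _HAVE_NUMBA:
            return float(_edge_ss(x, self.eu, self.ev))
        d = x[e[:, 0]] - x[e[:, 1]]
        return float(d @ d)

    def _update_shared_transfer(self) -> None:
        """Joint translation exploring shared-vs-specific attribution.

        Moves theta by a smooth random direction w (a unit-scale draw from
        the ICAR basis) while shifting s1 by -delta*w and s2 by -w/delta,
        which leaves both linear predictors exactly unchanged.  Acceptance
        is driven by the three ICAR priors.  The split of smooth risk
        between the shared field and the specific structured fields is
        only weakly likelihood-identified, so without this move the
        variance-fraction statistic mixes extremely slowly.
        """
        if self._icar_basis is None:
            return
        st = self.state
        z = self.rng.standard_normal(self._icar_basis.shape[1])
        w = np.exp(self.ls_transfer) * (self._icar_basis @ z)
        dprior = (
            -0.5 * st.tau_theta * self._delta_ss_after_shift(st.theta, w)
            - 0.5 * st.tau_s[0] * self._delta_ss_after_shift(st.s[0], -st.delta * w)
            - 0.5 * st.tau_s[1] * self._delta_ss_after_shift(st.s[1], -w / st.delta)
        )
        if np.log(self.rng.random()) < dprior:
            st.theta += w
            st.s[0] -= st.delta * w
            st.s[1] -= w / st.delta
            self.acc_transfer += 1
            self.n_acc_total["transfer"] += 1

    def _update_delta_theta_rescale(self) -> None:
        """Joint move trading delta against the scale of the shared field.

        Proposes log delta' = log delta + eps with theta' = theta * e^-eps,
        which keeps outcome 1's shared term delta*theta fixed; the implied
        change of outcome 2's term theta/delta is absorbed into u2.  The
        likelihood cancels exactly; the acceptance ratio carries the ICAR
        prior of theta, the u2 prior, the log-delta prior, and the
        Jacobian e^{-rank*eps} of scaling theta on its constraint manifold.
        """
        st = self.state
        eps = np.exp(self.ls_rescale) * self.rng.standard_normal()
        c = np.exp(eps)
        ld = np.log(st.delta)
        theta_new = st.theta / c
        shared2_old = st.theta / st.delta
        shared2_new = theta_new / (st.delta * c)
        u2n = st.u[1] + shared2_old - shared2_new
        ss = self._edge_sumsq(st.theta)
        dprior = (
            -0.5 * st.tau_theta * ss * (1.0 / c**2 - 1.0)
            - 0.5 * st.tau_u[1] * float(u2n @ u2n - st.u[1] @ st.u[1])
            - 0.5 * ((ld + eps) ** 2 - ld**2) / self.spec.priors.logdelta_prior_sd**2
            - self.rank * eps
        )
        if np.log(self.rng.random()) < dprior:
            st.delta = float(np.exp(ld + eps))
            st.theta = theta_new
            st.u[1] = u2n
            self.acc_rescale += 1
            self.n_acc_total["rescale"] += 1

    # -- precisions (exact Gibbs) ---------------------------------------

    def _gibbs_precisions(self) -> None:
        st = self.state
        pr = self.spec.priors
        icar_ss = self._edge_sumsq

        if self.spec.family == "shared":
            st.tau_theta = self.rng.gamma(
                pr.tau_gamma_shape + 0.5 * self.rank,
                1.0 / (pr.tau_gamma_rate + 0.5 * icar_ss(st.theta)),
            )
        for k in range(self.K):
            st.tau_s[k] = self.rng.gamma(
                pr.tau_gamma_shape + 0.5 * self.rank,
                1.0 / (pr.tau_gamma_rate + 0.5 * icar_ss(st.s[k])),
            )
            st.tau_u[k] = self.rng.gamma(
                pr.u_tau_gamma_shape + 0.5 * self.n,
                1.0 / (pr.u_tau_gamma_rate + 0.5 * float(st.u[k] @ st.u[k])),
            )

    # -- re-centering with intercept absorption -------------------------

    def _recenter(self) -> None:
        st = self.state
        if self.spec.family == "shared":
            m = float(st.theta.mean())
            st.theta -= m
            st.alpha[0] += st.delta * m
            st.alpha[1] += m / st.delta
        for k in range(self.K):
            m = float(st.s[k].mean())
            st.s[k] -= m
            st.alpha[k] += m
        # eta is invariant by construction; nothing to update

    # -- adaptation ------------------------------------------------------

    def _adapt(self) -> None:
        self.batch += 1
        inc = min(0.25, 1.0 / np.sqrt(self.batch))
        w = self.cfg.adapt_window
        for f in self.field_names:
            rate = self.acc[f] / w
            self.ls[f] += np.where(rate > self.cfg.target_accept, inc, -inc)
            self.scales[f] = np.exp(self.ls[f])
            self.acc[f][:] = 0.0
        self.ls_delta += inc if self.acc_delta / w > self.cfg.target_accept else -inc
        self.acc_delta = 0.0
        self.ls_ridge += inc if self.acc_ridge / w > self.cfg.target_accept else -inc
        self.acc_ridge = 0.0
        self.ls_transfer += inc if self.acc_transfer / w > self.cfg.target_accept else -inc
        self.acc_transfer = 0.0
        self.ls_rescale += inc if self.acc_rescale / w > self.cfg.target_accept else -inc
        self.acc_rescale = 0.0
        # scalar blocks behave like single-site updates; use the higher target
        block_target = (
            self.cfg.target_accept if self._block_dim() == 1 else self.cfg.block_target_accept
        )
        self.ls_block += inc if self.acc_block / w > block_target else -inc
        self.acc_block = 0.0
        self.ls_bridge += inc if self.acc_bridge / w > block_target else -inc
        self.acc_bridge = 0.0
        self._refresh_block_chol()

    # -- main loop -------------------------------------------------------

    def run(self) -> tuple[dict[str, np.ndarray], dict[str, float]]:
        cfg = self.cfg
        m = cfg.n_retained
        st = self.state
        out: dict[str, np.ndarray] = {
            "alpha": np.empty((m, self.K)),
            "beta": np.empty((m,) + st.beta.shape),
            "loglam": np.empty((m, self.n, self.K)),
        }
        for k in range(self.K):
            out[f"s{k + 1}"] = np.empty((m, self.n))
            out[f"u{k + 1}"] = np.empty((m, self.n))
            out[f"tau_s{k + 1}"] = np.empty(m)
            out[f"tau_u{k + 1}"] = np.empty(m)
        if self.spec.family == "shared":
            out["theta"] = np.empty((m, self.n))
            out["delta"] = np.empty(m)
            out["tau_theta"] = np.empty(m)

        if not np.all(np.isfinite(self.eta)):
            raise RuntimeError("non-finite log posterior at initialization")

        kept = 0
        for it in range(cfg.n_iter):
            if cfg.update_fields:
                self._update_fields()
            if cfg.update_regression:
                self._update_block()
                if cfg.update_fields and cfg.update_only is None:
                    self._update_block_ridge()
            if cfg.update_delta and self.spec.family == "shared":
                self._update_delta()
                if cfg.update_fields and cfg.update_only is None:
                    self._update_delta_ridge()
                    self._update_delta_theta_rescale()
            if cfg.update_fields and cfg.update_only is None and self.spec.family == "shared":
                self._update_shared_transfer()
            if cfg.update_precisions:
                self._gibbs_precisions()
            if cfg.update_fields:
                self._recenter()
            in_burnin = it < cfg.n_burnin
            if in_burnin:
                if cfg.update_regression:
                    self._accumulate_block_cov()
                if (it + 1) % cfg.adapt_window == 0:
                    self._adapt()
            else:
                if (it - cfg.n_burnin) % cfg.thin == 0:
                    out["alpha"][kept] = st.alpha
                    out["beta"][kept] = st.beta
                    out["loglam"][kept] = self.eta
                    for k in range(self.K):
                        out[f"s{k + 1}"][kept] = st.s[k]
                        out[f"u{k + 1}"][kept] = st.u[k]
                        out[f"tau_s{k + 1}"][kept] = st.tau_s[k]
                        out[f"tau_u{k + 1}"][kept] = st.tau_u[k]
                    if self.spec.family == "shared":
                        out["theta"][kept] = st.theta
                        out["delta"][kept] = st.delta
                        out["tau_theta"][kept] = st.tau_theta
                    kept += 1
        assert kept == m
        rates = {
            name: self.n_acc_total[name] / (cfg.n_iter * (self.n if name in self.field_names else 1))
            for name in self.n_acc_total
        }
        return out, rates


def run_mcmc(spec: ModelSpec, data: ArealDataset, config: MCMCConfig) -> PosteriorSamples:
    """Sample the posterior of ``spec`` on ``data``; deterministic given seed.

    Chains draw from independent streams spawned from ``config.seed``.
    """
    if spec.family == "shared" and data.n_outcomes != 2:
        raise ValueError("shared family requires a two-outcome dataset")
    ss = np.random.SeedSequence(config.seed)
    chains = []
    rates = []
    for child in ss.spawn(config.n_chains):
        sampler = _Sampler(spec, data, config, np.random.default_rng(child))
        draws, acc = sampler.run()
        chains.append(draws)
        rates.append(acc)
    return PosteriorSamples(spec, config, chains, rates, list(data.graph.area_ids))


# --------------------------------------------------------------------------
# diagnostics and DIC


def _extract_scalar(chain: dict[str, np.ndarray], name: str, index=None) -> np.ndarray:
    arr = chain[name]
    if index is not None:
        arr = arr[(slice(None),) + (index if isinstance(index, tuple) else (index,))]
    if arr.ndim != 1:
        raise ValueError(f"{name!r} with index {index!r} is not scalar per draw")
    return arr


def gelman_rubin(samples: PosteriorSamples, name: str, index=None) -> float:
    """Potential scale reduction factor (between/within chain variance).

    Computed from the whole retained chains (not split), clamped below at
    1.0 so that identical chains report exactly 1.  Returns +inf when the
    within-chain variance is zero but chains disagree.
    """
    if samples.n_chains < 2:
        raise ValueError("gelman_rubin requires at least 2 chains")
    seqs = np.stack([_extract_scalar(c, name, index) for c in samples.chains])
    mchains, ndraw = seqs.shape
    if ndraw < 2:
        raise ValueError("need at least 2 draws per chain")
    chain_means = seqs.mean(axis=1)
    W = float(seqs.var(axis=1, ddof=1).mean())
    B = float(ndraw * chain_means.var(ddof=1)) if mchains > 1 else 0.0
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    var_plus = (ndraw - 1) / ndraw * W + B / ndraw
    return max(1.0, float(np.sqrt(var_plus / W)))


def diagnostics(samples: PosteriorSamples, names: list[str] | None = None) -> ChainDiagnostics:
    """R-hat and effective sample size for the scalar parameters.

    ESS uses arviz's autocorrelation estimator on the retained chains.
    """
    import arviz as az

    if names is None:
        names = [
            n
            for n in samples.parameter_names()
            if samples.chains[0][n].ndim == 1
        ]
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    for n in names:
        seqs = np.stack([c[n] for c in samples.chains])
        if samples.n_chains >= 2:
            rhat[n] = gelman_rubin(samples, n)
        ess[n] = float(az.ess(az.convert_to_dataset(seqs))["x"].values)
    return ChainDiagnostics(rhat, ess, samples.acceptance)


def _deviance(O: np.ndarray, loglam: np.ndarray) -> float:
    """-2 * sum[O log lam - lam], omitting the data-only log O! term."""
    return float(-2.0 * np.sum(O * loglam - np.exp(loglam)))


def compute_dic(
    samples: PosteriorSamples, spec: ModelSpec, data: ArealDataset, outcome: str = "k1"
) -> dict[str, float]:
    """Deviance information criterion for the selected outcome(s).

    ``D(state) = -2 log L`` for the chosen outcome(s) with the log O!
    constant omitted consistently; ``Dbar`` is its posterior mean, the
    plug-in deviance is evaluated at the posterior-mean linear predictor
    (classic Spiegelhalter pD), and ``DIC = Dbar + pD``.  ``outcome`` is
    'k1', 'k2', or 'both'.
    """
    loglam = samples.stacked("loglam")  # (m, n, K)
    if loglam.shape[0] == 0:
        raise ValueError("empty samples")
    K = loglam.shape[2]
    if outcome == "both":
        ks = list(range(K))
    elif outcome in ("k1", "k2"):
        ks = [int(outcome[1]) - 1]
        if ks[0] >= K:
            raise ValueError(f"outcome {outcome} not present (model has {K})")
    else:
        raise ValueError("outcome must be 'k1', 'k2', or 'both'")
    O = data.O[:, ks].astype(float)
    ll = loglam[:, :, ks]
    d_draws = -2.0 * np.sum(O[None] * ll - np.exp(ll), axis=(1, 2))
    dbar = float(d_draws.mean())
    dhat = _deviance(O, ll.mean(axis=0))
    pd_ = dbar - dhat
    # degenerate chains give pD = 0 up to summation round-off; snap it
    if abs(pd_) < 1e-10 * max(1.0, abs(dbar)):
        pd_ = 0.0
    return {"Dbar": dbar, "pD": pd_, "DIC": dbar + pd_}
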