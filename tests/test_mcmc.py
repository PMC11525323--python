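"""Sampler correctness: determinism, conjugacy, quadrature oracles, DIC, R-hat."""

import numpy as np
import pytest
import scipy.stats as sps

from sharedmap import ArealDataset, MCMCConfig, compute_dic, gelman_rubin, run_mcmc
from sharedmap.mcmc import PosteriorSamples, _Sampler
from sharedmap.models import ModelSpec, PriorConfig, initial_state, model_number_spec
from sharedmap.spatial import AdjacencyGraph, build_lattice_adjacency, graph_from_id_lists


def one_area_dataset(O=7, E=2.0):
    g = AdjacencyGraph(1, ["a"], [np.array([], dtype=int)])
    return ArealDataset(g, np.array([[O]]), np.array([[E]]), np.empty((1, 0)))


def two_area_dataset():
    g = graph_from_id_lists(["a", "b"], {"a": ["b"], "b": ["a"]})
    O = np.array([[12, 8], [3, 9]])
    E = np.full((2, 2), 5.0)
    return ArealDataset(g, O, E, np.empty((2, 0)))


def intercept_posterior_quadrature(O=7.0, E=2.0, prior_sd=31.6227766016838):
    """Oracle: Poisson(O | E e^b) x Normal(0, prior_sd^2) posterior moments of b
    by 1-d numerical quadrature."""
    b = np.linspace(-6.0, 6.0, 200_001)
    logpost = O * b - E * np.exp(b) - 0.5 * b**2 / prior_sd**2
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    mean = float(np.sum(w * b))
    sd = float(np.sqrt(np.sum(w * (b - mean) ** 2)))
    return mean, sd, b, w


class TestDeterminism:
    def test_same_seed_reproduces_draws_exactly(self, small_dataset):
        spec = model_number_spec(4)
        cfg = MCMCConfig(n_chains=2, n_iter=300, n_burnin=100, thin=2, seed=17)
        s1 = run_mcmc(spec, small_dataset, cfg)
        s2 = run_mcmc(spec, small_dataset, cfg)
        for c1, c2 in zip(s1.chains, s2.chains):
            for name in c1:
                np.testing.assert_array_equal(c1[name], c2[name])

    def test_different_seeds_differ(self, small_dataset):
        spec = model_number_spec(3)
        a = run_mcmc(spec, small_dataset, MCMCConfig(n_chains=1, n_iter=200, n_burnin=50, seed=1))
        b = run_mcmc(spec, small_dataset, MCMCConfig(n_chains=1, n_iter=200, n_burnin=50, seed=2))
        assert not np.array_equal(a.stacked("delta"), b.stacked("delta"))


class TestQuadratureOracles:
    def test_one_area_intercept_posterior(self):
        """Posterior mean/sd of the intercept in a one-area Poisson model
        match 1-d quadrature within 2%."""
        data = one_area_dataset()
        spec = ModelSpec(family="bym", include_covariates=False)
        cfg = MCMCConfig(
            n_chains=1, n_iter=24_000, n_burnin=4_000, thin=1, seed=5,
            update_fields=False, update_precisions=False,
        )
        samples = run_mcmc(spec, data, cfg)
        draws = samples.stacked("alpha")[:, 0]
        mean, sd, _, _ = intercept_posterior_quadrature()
        assert draws.mean() == pytest.approx(mean, rel=0.02)
        assert draws.std() == pytest.approx(sd, rel=0.02)

    def test_two_area_theta_posterior(self):
        """With only the shared field free on a 2-area graph, the posterior of
        the centred direction t = theta_1 matches quadrature within 2%."""
        data = two_area_dataset()
        spec = ModelSpec(family="shared", include_covariates=False)
        cfg = MCMCConfig(
            n_chains=1, n_iter=44_000, n_burnin=4_000, thin=2, seed=6,
            update_only=("theta",), update_regression=False,
            update_delta=False, update_precisions=False,
        )
        samples = run_mcmc(spec, data, cfg)
        t_draws = samples.stacked("theta")[:, 0]

        # oracle: p(t) prop. to ICAR(t) * prod_k int lik_k(a_k, t) da_k,
        # flat in the absorbed intercept direction
        tau = 10.0  # the sampler's fixed initial precision
        tgrid = np.linspace(-2.0, 2.0, 4001)
        agrid = np.linspace(-5.0, 5.0, 2001)
        logp = -2.0 * tau * tgrid**2  # -tau/2 * (2t)^2
        for k, sign in ((0, 1.0), (1, 1.0)):
            O1, O2 = data.O[0, k], data.O[1, k]
            E = data.E[0, k]
            ll = (
                (O1 + O2) * agrid[None, :]
                + (O1 - O2) * tgrid[:, None]
                - E * np.exp(agrid[None, :])
                * (np.exp(tgrid[:, None]) + np.exp(-tgrid[:, None]))
            )
            m = ll.max()
            logp += m + np.log(np.trapezoid(np.exp(ll - m), agrid, axis=1))
        w = np.exp(logp - logp.max())
        w /= w.sum()
        mean = float(np.sum(w * tgrid))
        sd = float(np.sqrt(np.sum(w * (tgrid - mean) ** 2)))
        assert t_draws.mean() == pytest.approx(mean, rel=0.02, abs=0.02 * abs(mean))
        assert t_draws.std() == pytest.approx(sd, rel=0.02)


class TestConjugacy:
    def test_precision_gibbs_matches_gamma_full_conditional(self):
        """Holding all fields fixed, repeated precision draws follow the
        analytic Gamma((a + rank/2), b + SS/2) full conditionals."""
        g = build_lattice_adjacency(4, 4, "rook")
        rng = np.random.default_rng(3)
        O = rng.poisson(5.0, (16, 2))
        data = ArealDataset(g, O, np.full((16, 2), 5.0), np.empty((16, 0)))
        spec = model_number_spec(3)
        cfg = MCMCConfig(n_chains=1, n_iter=10, n_burnin=5, seed=0)
        sampler = _Sampler(spec, data, cfg, np.random.default_rng(12))
        st = sampler.state
        t = rng.standard_normal(16)
        st.theta = t - t.mean()
        s = rng.standard_normal(16)
        st.s[0] = s - s.mean()
        st.u[0] = 0.5 * rng.standard_normal(16)

        n_draws = 5000
        draws = {"tau_theta": [], "tau_s1": [], "tau_u1": []}
        for _ in range(n_draws):
            sampler._gibbs_precisions()
            draws["tau_theta"].append(st.tau_theta)
            draws["tau_s1"].append(st.tau_s[0])
            draws["tau_u1"].append(st.tau_u[0])

        pr = spec.priors
        rank = 15  # 16 areas, 1 component
        e = g.edges
        for name, x, shape, rate in [
            ("tau_theta", st.theta, pr.tau_gamma_shape + rank / 2, None),
            ("tau_s1", st.s[0], pr.tau_gamma_shape + rank / 2, None),
            ("tau_u1", st.u[0], pr.u_tau_gamma_shape + 16 / 2, None),
        ]:
            if name == "tau_u1":
                rate = pr.u_tau_gamma_rate + 0.5 * float(x @ x)
            else:
                d = x[e[:, 0]] - x[e[:, 1]]
                rate = pr.tau_gamma_rate + 0.5 * float(d @ d)
            stat, p = sps.kstest(draws[name], sps.gamma(a=shape, scale=1.0 / rate).cdf)
            assert p > 0.01, f"{name}: KS p={p}"


class TestPriorRecovery:
    def test_tau_u_matches_prior_moments_without_likelihood(self):
        """With the likelihood disabled the sampler's marginal precision draws
        reproduce the Gamma prior's mean within Monte-Carlo error."""
        g = build_lattice_adjacency(3, 3, "rook")
        data = ArealDataset(g, np.ones((9, 1)), np.ones((9, 1)), np.empty((9, 0)))
        priors = PriorConfig(u_tau_gamma_shape=3.0, u_tau_gamma_rate=2.0)
        spec = ModelSpec(family="bym", include_covariates=False, priors=priors)
        cfg = MCMCConfig(
            n_chains=1, n_iter=20_000, n_burnin=2_000, thin=2, seed=9,
            use_likelihood=False, update_regression=False, update_only=("u1",),
        )
        samples = run_mcmc(spec, data, cfg)
        tau = samples.stacked("tau_u1")
        prior_mean, prior_sd = 1.5, np.sqrt(3.0) / 2.0
        se = 3.0 * prior_sd / np.sqrt(200.0)  # conservative ESS guess
        assert abs(tau.mean() - prior_mean) < se


class TestRecentering:
    def test_recentering_preserves_poisson_means(self, small_dataset):
        spec = model_number_spec(3)
        cfg = MCMCConfig(n_chains=1, n_iter=10, n_burnin=5, seed=0)
        sampler = _Sampler(spec, small_dataset, cfg, np.random.default_rng(4))
        st = sampler.state
        rng = np.random.default_rng(5)
        st.theta = rng.standard_normal(4) * 0.5  # deliberately uncentred
        st.s[0] = rng.standard_normal(4) * 0.3
        st.s[1] = rng.standard_normal(4) * 0.3
        st.delta = 1.4
        sampler.eta = sampler._full_eta()
        lam_before = np.exp(sampler.eta.copy())
        sampler._recenter()
        lam_after = np.exp(sampler._full_eta())
        np.testing.assert_allclose(lam_after, lam_before, rtol=1e-10)
        assert abs(st.theta.sum()) < 1e-12
        assert abs(st.s[0].sum()) < 1e-12

    def test_disconnected_graph_rejected(self):
        g = graph_from_id_lists(
            ["a", "b", "c", "d"], {"a": ["b"], "b": ["a"], "c": ["d"], "d": ["c"]}
        )
        data = ArealDataset(g, np.ones((4, 2)), np.ones((4, 2)), np.empty((4, 0)))
        with pytest.raises(ValueError, match="connected"):
            run_mcmc(model_number_spec(3), data, MCMCConfig(n_chains=1, n_iter=10, n_burnin=5))


def _samples_from_chains(chains):
    spec = ModelSpec(family="shared", include_covariates=False)
    cfg = MCMCConfig(n_chains=len(chains), n_iter=2, n_burnin=1)
    return PosteriorSamples(
        spec, cfg, [{"delta": np.asarray(c, dtype=float)} for c in chains], [{}]
    )


class TestGelmanRubin:
    def test_identical_chains_give_exactly_one(self):
        rng = np.random.default_rng(0)
        c = rng.standard_normal(500)
        samples = _samples_from_chains([c, c.copy()])
        assert gelman_rubin(samples, "delta") == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_constant_chains_diverge(self):
        samples = _samples_from_chains([np.zeros(100), np.ones(100)])
        assert gelman_rubin(samples, "delta") == np.inf

    def test_iid_normal_chains_near_one(self):
        rng = np.random.default_rng(1)
        samples = _samples_from_chains([rng.standard_normal(10_000) for _ in range(2)])
        assert 0.99 <= gelman_rubin(samples, "delta") <= 1.01

    def test_single_chain_rejected(self):
        samples = _samples_from_chains([np.zeros(10)])
        with pytest.raises(ValueError):
            gelman_rubin(samples, "delta")

    def test_agrees_with_arviz_on_mixed_chains(self):
        import arviz as az

        rng = np.random.default_rng(2)
        chains = [rng.standard_normal(5000) for _ in range(4)]
        samples = _samples_from_chains(chains)
        mine = gelman_rubin(samples, "delta")
        theirs = float(az.rhat(az.convert_to_dataset(np.stack(chains)))["x"])
        assert mine == pytest.approx(theirs, abs=0.01)


class TestDIC:
    def _degenerate_samples(self, data, spec):
        n, K = data.n_areas, 2
        loglam = np.log(data.E[:, :K]) + 0.3
        chain = {
            "loglam": np.tile(loglam, (50, 1, 1)),
            "delta": np.ones(50),
        }
        cfg = MCMCConfig(n_chains=1, n_iter=2, n_burnin=1)
        return PosteriorSamples(spec, cfg, [chain], [{}])

    def test_degenerate_chain_has_zero_pd(self, small_dataset):
        spec = model_number_spec(3)
        samples = self._degenerate_samples(small_dataset, spec)
        res = compute_dic(samples, spec, small_dataset, "k1")
        assert res["pD"] == 0.0
        assert res["DIC"] == res["Dbar"]

    def test_outcome_additivity(self, small_dataset):
        spec = model_number_spec(3)
        cfg = MCMCConfig(n_chains=1, n_iter=400, n_burnin=100, thin=2, seed=3)
        samples = run_mcmc(spec, small_dataset, cfg)
        d1 = compute_dic(samples, spec, small_dataset, "k1")
        d2 = compute_dic(samples, spec, small_dataset, "k2")
        db = compute_dic(samples, spec, small_dataset, "both")
        assert d1["DIC"] + d2["DIC"] == pytest.approx(db["DIC"], abs=1e-8)

    def test_one_area_dic_matches_quadrature(self):
        """DIC of the one-area intercept model agrees with a quadrature-computed
        Dbar and pD within 2%."""
        data = one_area_dataset()
        spec = ModelSpec(family="bym", include_covariates=False)
        cfg = MCMCConfig(
            n_chains=1, n_iter=24_000, n_burnin=4_000, thin=1, seed=8,
            update_fields=False, update_precisions=False,
        )
        samples = run_mcmc(spec, data, cfg)
        res = compute_dic(samples, spec, data, "k1")

        O, E = 7.0, 2.0
        _, _, b, w = intercept_posterior_quadrature()
        loglam = np.log(E) + b
        d = -2.0 * (O * loglam - np.exp(loglam))
        dbar = float(np.sum(w * d))
        loglam_bar = float(np.sum(w * loglam))
        dhat = -2.0 * (O * loglam_bar - np.exp(loglam_bar))
        pd_ = dbar - dhat
        assert res["Dbar"] == pytest.approx(dbar, rel=0.02)
        assert res["pD"] == pytest.approx(pd_, rel=0.02, abs=0.02)
        assert res["DIC"] == pytest.approx(dbar + pd_, rel=0.02)

    def test_empty_samples_rejected(self, small_dataset):
        spec = model_number_spec(3)
        cfg = MCMCConfig(n_chains=1, n_iter=2, n_burnin=1)
        empty = PosteriorSamples(
            spec, cfg, [{"loglam": np.empty((0, 4, 2)), "delta": np.empty(0)}], [{}]
        )
        with pytest.raises(ValueError):
            compute_dic(empty, spec, small_dataset, "k1")
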