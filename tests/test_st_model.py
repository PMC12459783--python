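"""Likelihood, model assembly, joint posterior density and the sampler."""
import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from carst.rates_smr import CountPanel, expected_counts
from carst.st_model import (
    LatentState,
    ModelSpec,
    build_model,
    fit_mcmc,
    log_posterior,
    nb1_loglik,
    posterior_summary,
)
from carst.synthetic_data import grid_graph


def make_panel(n, T, seed=0, mean=5.0):
    rng = np.random.default_rng(seed)
    Y = rng.poisson(mean, (n, T))
    if Y.sum() == 0:
        Y[0, 0] = 1
    P = rng.uniform(5_000, 50_000, (n, T))
    return expected_counts(CountPanel(tuple(f"a{i}" for i in range(n)),
                                      tuple(range(2000, 2000 + T)), Y, P))


class TestNb1Loglik:
    def test_poisson_limit(self):
        assert nb1_loglik(2, 2.0, 1.0) == pytest.approx(np.log(4 * np.exp(-2) / 2),
                                                        abs=1e-9)
        assert nb1_loglik(2, 2.0, 1.0) == pytest.approx(-1.30685, abs=1e-4)

    def test_geometric_closed_form(self):
        # mu=1, r=2 -> kappa=1, p=1/2: P(Y=0) = 1/2
        assert nb1_loglik(0, 1.0, 2.0) == pytest.approx(np.log(0.5), abs=1e-12)

    @pytest.mark.parametrize("y,mu,r", [(0, 0.5, 3.0), (4, 2.5, 1.7), (11, 8.0, 6.0)])
    def test_matches_scipy_nbinom(self, y, mu, r):
        kappa = mu / (r - 1.0)
        expect = stats.nbinom.logpmf(y, kappa, 1.0 / r)
        assert nb1_loglik(y, mu, r) == pytest.approx(expect, abs=1e-10)

    def test_sampled_moments(self):
        # gamma-Poisson mixture reproduces mean mu and variance r*mu
        rng = np.random.default_rng(8)
        mu, r = 4.0, 3.0
        lam = rng.gamma(mu / (r - 1), r - 1, size=400_000)
        y = rng.poisson(lam)
        assert y.mean() == pytest.approx(4.0, abs=0.05)
        assert y.var() == pytest.approx(12.0, rel=0.03)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nb1_loglik(1, -1.0, 2.0)
        with pytest.raises(ValueError):
            nb1_loglik(1, 1.0, 0.5)


class TestBuildModel:
    def test_interaction_none_has_no_delta(self):
        panel = make_panel(4, 4)
        model = build_model(panel, grid_graph(2, 2), ModelSpec(interaction="none"))
        assert "delta" not in model.blocks

    def test_type_iv_constraint_count(self):
        n, T = 12, 5
        panel = make_panel(n, T)
        model = build_model(panel, grid_graph(3, 4),
                            ModelSpec(interaction="IV"))
        b = model.blocks["delta"]
        assert b.m == n * T
        assert b.rank == (n - 1) * (T - 2)
        assert b.m - b.rank == n * T - (n - 1) * (T - 2)

    def test_requires_expected_counts(self):
        panel = make_panel(4, 4)
        bare = CountPanel(panel.areas, panel.years, panel.Y, panel.P)
        with pytest.raises(ValueError, match="expected"):
            build_model(bare, grid_graph(2, 2), ModelSpec())

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="areas"):
            build_model(make_panel(4, 4), grid_graph(2, 3), ModelSpec())

    def test_rw2_needs_three_years(self):
        with pytest.raises(ValueError, match="3 years"):
            build_model(make_panel(4, 2), grid_graph(2, 2), ModelSpec())


def oracle_log_posterior(model, state):
    """Term-by-term independent recomputation of the joint log density."""
    panel, graph, spec = model.panel, model.graph, model.spec
    n, T = panel.n_areas, panel.n_years
    eta = state.alpha + np.zeros((n, T))
    if state.U is not None:
        eta += state.U[:, None]
    if state.V is not None:
        eta += state.V[:, None]
    if state.gamma is not None:
        eta += state.gamma[None, :]
    if state.phi is not None:
        eta += state.phi[None, :]
    if state.delta is not None:
        eta += state.delta
    mu = panel.E * np.exp(eta)
    r = state.r
    if spec.likelihood == "poisson" or r <= 1 + 1e-8:
        lp = float(stats.poisson.logpmf(panel.Y, mu).sum())
    else:
        kappa = mu / (r - 1)
        lp = float(stats.nbinom.logpmf(panel.Y, kappa, 1 / r).sum())

    def intrinsic(x, R, tau):
        vals = np.linalg.eigvalsh(R)
        nz = vals[vals > 1e-9 * max(vals.max(), 1)]
        rank = nz.size
        return (0.5 * rank * np.log(tau / (2 * np.pi))
                + 0.5 * np.sum(np.log(nz)) - 0.5 * tau * x @ R @ x)

    A = graph.adjacency()
    R_icar = np.diag(A.sum(1)) - A
    D = np.zeros((T - 2, T))
    for k in range(T - 2):
        D[k, k:k + 3] = (1, -2, 1)
    R_rw2 = D.T @ D

    if state.U is not None:
        lp += float(stats.norm.logpdf(state.U, 0, 1 / np.sqrt(state.tau["U"])).sum())
    if state.V is not None:
        lp += intrinsic(state.V, R_icar, state.tau["V"])
    if state.gamma is not None:
        lp += intrinsic(state.gamma, R_rw2, state.tau["gamma"])
    if state.phi is not None:
        lp += float(stats.norm.logpdf(state.phi, 0, 1 / np.sqrt(state.tau["phi"])).sum())
    if state.delta is not None:
        d = state.delta.ravel()
        tau = state.tau["delta"]
        if spec.interaction == "I":
            lp += float(stats.norm.logpdf(d, 0, 1 / np.sqrt(tau)).sum())
        else:
            R = {"II": np.kron(np.eye(n), R_rw2),
                 "III": np.kron(R_icar, np.eye(T)),
                 "IV": np.kron(R_icar, R_rw2)}[spec.interaction]
            lp += intrinsic(d, R, tau)
    a, b = spec.prior_shape, spec.prior_rate
    for tau in state.tau.values():
        lp += a * np.log(b) - gammaln(a) + a * np.log(tau) - b * tau
    lp += float(stats.norm.logpdf(state.alpha, 0, spec.intercept_sd))
    if spec.likelihood == "negbin":
        lp += float(stats.norm.logpdf(np.log(r - 1), 0, spec.logr_sd))
    return lp


def random_constrained_state(model, rng):
    """Random latent state whose intrinsic components satisfy constraints."""
    n, T = model.n, model.T
    vals = {}
    for name, b in model.blocks.items():
        xi = rng.standard_normal(b.rank) * 0.3
        vals[name] = b.full(xi)
    return LatentState(
        alpha=float(rng.normal(0, 0.3)),
        U=vals.get("U"), V=vals.get("V"),
        gamma=vals.get("gamma"), phi=vals.get("phi"),
        delta=vals["delta"].reshape(n, T) if "delta" in vals else None,
        r=float(1 + rng.gamma(2, 0.5)) if model.spec.likelihood == "negbin" else 1.0,
        tau={name: float(rng.gamma(3, 2)) for name in model.blocks},
    )


class TestLogPosterior:
    @pytest.mark.parametrize("itype", ["none", "I", "II", "III", "IV"])
    @pytest.mark.parametrize("likelihood", ["poisson", "negbin"])
    def test_matches_term_by_term_oracle(self, itype, likelihood):
        panel = make_panel(4, 4, seed=3)
        model = build_model(panel, grid_graph(2, 2),
                            ModelSpec(likelihood=likelihood, interaction=itype))
        rng = np.random.default_rng(17)
        for _ in range(4):
            state = random_constrained_state(model, rng)
            assert log_posterior(model, state) == pytest.approx(
                oracle_log_posterior(model, state), abs=1e-8)

    def test_precision_change_only_affects_its_family(self):
        panel = make_panel(4, 4, seed=1)
        model = build_model(panel, grid_graph(2, 2), ModelSpec(interaction="IV"))
        rng = np.random.default_rng(2)
        state = random_constrained_state(model, rng)
        base = log_posterior(model, state)
        state2 = random_constrained_state(model, rng)
        # same state except tau_U
        for f in ("U", "V", "gamma", "phi", "delta"):
            setattr(state2, f if f != "delta" else "delta",
                    getattr(state, f))
        state2.alpha, state2.r = state.alpha, state.r
        state2.tau = dict(state.tau)
        state2.tau["U"] = state.tau["U"] * 2.5
        diff = log_posterior(model, state2) - base
        expect = (oracle_log_posterior(model, state2)
                  - oracle_log_posterior(model, state))
        assert diff == pytest.approx(expect, abs=1e-9)

    def test_predictor_shift_invariance_of_likelihood(self):
        # adding c to alpha and subtracting it from phi leaves eta unchanged
        panel = make_panel(4, 4, seed=5)
        model = build_model(panel, grid_graph(2, 2), ModelSpec(interaction="I"))
        rng = np.random.default_rng(4)
        s1 = random_constrained_state(model, rng)
        from carst.st_model import _loglik_eta, linear_predictor

        eta1 = linear_predictor(model, s1)
        s1.alpha += 0.7
        s1.phi = s1.phi - 0.7
        eta2 = linear_predictor(model, s1)
        np.testing.assert_allclose(eta1, eta2, atol=1e-12)
        assert _loglik_eta(model, eta1, s1.r) == pytest.approx(
            _loglik_eta(model, eta2, s1.r))


class TestFitMcmc:
    def test_same_seed_identical_draws(self):
        panel = make_panel(4, 4, seed=2)
        model = build_model(panel, grid_graph(2, 2),
                            ModelSpec(likelihood="negbin", interaction="I"))
        d1 = fit_mcmc(model, chains=1, iterations=120, burn_in=40, thin=1,
                      seed=5, compute_diagnostics=False)
        d2 = fit_mcmc(model, chains=1, iterations=120, burn_in=40, thin=1,
                      seed=5, compute_diagnostics=False)
        np.testing.assert_array_equal(d1.alpha, d2.alpha)
        np.testing.assert_array_equal(d1.delta, d2.delta)
        np.testing.assert_array_equal(d1.r, d2.r)

    def test_constraints_hold_in_every_draw(self):
        panel = make_panel(6, 5, seed=3)
        graph = grid_graph(2, 3)
        model = build_model(panel, graph,
                            ModelSpec(likelihood="poisson", interaction="IV"))
        draws = fit_mcmc(model, chains=1, iterations=150, burn_in=50, thin=1,
                         seed=1, compute_diagnostics=False)
        from carst.areal_graph import constraint_basis

        C = np.stack(constraint_basis("IV", graph, 5), axis=1)
        flat = draws.delta.reshape(draws.n_draws, -1)
        assert np.abs(flat @ C).max() < 1e-10
        # V sums to zero; gamma orthogonal to constant and linear trend
        assert np.abs(draws.effects["V"].sum(axis=1)).max() < 1e-10
        t = np.arange(5) - 2.0
        assert np.abs(draws.effects["gamma"] @ t).max() < 1e-9

    def test_shrinks_to_overall_smr_with_tiny_variances(self):
        # huge precisions force effects ~ 0: exp(alpha) ~ sum(Y)/sum(E)
        panel = make_panel(6, 5, seed=9, mean=8.0)
        graph = grid_graph(2, 3)
        spec = ModelSpec(likelihood="poisson", interaction="none",
                         prior_shape=5e4, prior_rate=5.0)
        model = build_model(panel, graph, spec)
        draws = fit_mcmc(model, chains=1, iterations=900, burn_in=300, thin=1,
                         seed=2, compute_diagnostics=False)
        overall = panel.Y.sum() / panel.E.sum()
        assert np.exp(draws.alpha.mean()) == pytest.approx(overall, rel=0.05)

    def test_iterations_must_exceed_burn_in(self):
        panel = make_panel(4, 4)
        model = build_model(panel, grid_graph(2, 2), ModelSpec())
        with pytest.raises(ValueError):
            fit_mcmc(model, iterations=100, burn_in=100)


class TestPosteriorSummary:
    @staticmethod
    def synthetic_draws(x):
        from carst.st_model import PosteriorDraws

        D = x.size
        return PosteriorDraws(alpha=x, effects={}, delta=None,
                              r=np.ones(D), tau={}, loglik=np.zeros((D, 1, 1)),
                              chain_id=np.zeros(D, int), areas=("a",),
                              years=(2000,), seed=0, interaction="none",
                              likelihood="poisson")

    def test_standard_normal_draws(self):
        rng = np.random.default_rng(0)
        draws = self.synthetic_draws(rng.standard_normal(20_000))
        s = posterior_summary(draws).loc["intercept"]
        assert s["mean"] == pytest.approx(0.0, abs=0.03)
        assert s["ci_low"] == pytest.approx(-1.96, abs=0.06)
        assert s["ci_high"] == pytest.approx(1.96, abs=0.06)
        assert s["mode"] == pytest.approx(0.0, abs=0.25)  # KDE argmax is noisy

    def test_constant_draws_degenerate(self):
        draws = self.synthetic_draws(np.full(200, 1.5))
        s = posterior_summary(draws).loc["intercept"]
        assert s["sd"] == 0.0 and s["ci_low"] == s["ci_high"] == 1.5

    def test_too_few_draws(self):
        with pytest.raises(ValueError, match="100"):
            posterior_summary(self.synthetic_draws(np.zeros(50)))
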