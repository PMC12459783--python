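"""Hierarchical negative-binomial spatio-temporal model and its MCMC sampler.

Observation model (NB1 parameterization)::

    Y_it | theta_it, r ~ NegBin(mean = mu_it, variance = r * mu_it)
    mu_it = E_it * theta_it
    log(theta_it) = alpha + U_i + V_i + gamma_t + phi_t + delta_it

with U iid normal, V intrinsic CAR on the contiguity graph, gamma a
second-order random walk over years, phi iid normal over years, and delta
one of the four Knorr-Held space-time interactions. Each random-effect
precision carries a Gamma(1, 0.001) prior (equivalently log-gamma on the
log precision); the intercept has a wide proper normal prior standing in
for a flat one; log(r - 1) is weakly-informative normal.

Every rank-deficient block is parameterized on the orthonormal basis of
its structure matrix's row space (x = K xi), so sum-to-zero / detrending
constraints hold exactly at every sweep and all reduced priors are
proper. The sampler is Metropolis-within-Gibbs: each latent family is
updated jointly from a Gaussian (iteratively-weighted-least-squares)
approximation of its full conditional with a Metropolis-Hastings
correction, precisions are conjugate Gamma draws, and the overdispersion
moves by an adaptive random walk on log(r - 1).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import digamma, gammaln

from .areal_graph import SpatialGraph, interaction_factors
from .rates_smr import CountPanel

__all__ = [
    "ModelSpec",
    "LatentState",
    "ModelDef",
    "PosteriorDraws",
    "nb1_loglik",
    "build_model",
    "log_posterior",
    "fit_mcmc",
    "posterior_summary",
]

_POISSON_EDGE = 1.0 + 1e-8  # r below this is treated as the Poisson limit
_ETA_CLIP = 40.0            # guard on the linear predictor before exp


@dataclass(frozen=True)
class ModelSpec:
    """Likelihood, interaction type and prior settings.

    ``components`` selects which main random effects enter the linear
    predictor (the interaction is governed separately by ``interaction``).
    ``prior_shape``/``prior_rate`` give the Gamma hyperprior on every
    random-effect precision. ``nb_variant`` switches between NB1
    (variance ``r * mu``, the default) and NB2 (variance
    ``mu + (r-1) * mu**2``) overdispersion forms.
    """

    likelihood: str = "negbin"
    interaction: str = "IV"
    prior_shape: float = 1.0
    prior_rate: float = 0.001
    intercept_sd: float = 1000.0
    logr_sd: float = 10.0
    icar_scaled: bool = False
    nb_variant: str = "nb1"
    components: tuple = ("U", "V", "gamma", "phi")

    def __post_init__(self):
        if self.likelihood not in ("negbin", "poisson"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.interaction not in ("none", "I", "II", "III", "IV"):
            raise ValueError(f"unknown interaction type {self.interaction!r}")
        if self.prior_shape <= 0 or self.prior_rate <= 0:
            raise ValueError("hyperprior shape and rate must be positive")
        bad = set(self.components) - {"U", "V", "gamma", "phi"}
        if bad:
            raise ValueError(f"unknown components {sorted(bad)}")


@dataclass
class LatentState:
    """One full configuration of the latent hierarchy (full-space arrays)."""

    alpha: float
    U: np.ndarray | None
    V: np.ndarray | None
    gamma: np.ndarray | None
    phi: np.ndarray | None
    delta: np.ndarray | None  # (n, T)
    r: float
    tau: dict


@dataclass
class _Block:
    """Internal: one latent Gaussian family in reduced coordinates."""

    name: str
    kind: str              # "area" | "year" | "cell"
    m: int                 # full dimension
    rank: int
    K: np.ndarray | None   # (m, rank) orthonormal basis; None == identity
    s_diag: np.ndarray     # prior structure eigenvalues in reduced space
    # Kronecker factors of K for interaction blocks (spatial, temporal)
    kron_factors: tuple | None = None

    @property
    def log_pdet(self) -> float:
        return float(np.sum(np.log(self.s_diag)))

    def full(self, xi: np.ndarray) -> np.ndarray:
        if self.K is None:
            return xi
        if self.kron_factors is not None:
            Pa, Pb = self.kron_factors
            return (Pa @ xi.reshape(Pa.shape[1], Pb.shape[1]) @ Pb.T).ravel()
        return self.K @ xi

    def reduce(self, x: np.ndarray) -> np.ndarray:
        if self.K is None:
            return x
        if self.kron_factors is not None:
            Pa, Pb = self.kron_factors
            return (Pa.T @ x.reshape(Pa.shape[0], Pb.shape[0]) @ Pb).ravel()
        return self.K.T @ x

    def bwb(self, w_reduced: np.ndarray) -> np.ndarray:
        """K' diag(w) K for the family-aggregated weight vector."""
        if self.kron_factors is not None:
            Pa, Pb = self.kron_factors
            W = w_reduced.reshape(Pa.shape[0], Pb.shape[0])
            M = np.einsum("tb,it,tc->ibc", Pb, W, Pb, optimize=True)
            out = np.einsum("ia,ibd,ic->abcd", Pa, M, Pa, optimize=True)
            return out.reshape(self.rank, self.rank)
        return (self.K * w_reduced[:, None]).T @ self.K


class ModelDef:
    """Assembled model: data vectors, family blocks, prior settings."""

    def __init__(self, panel: CountPanel, graph: SpatialGraph, spec: ModelSpec):
        if panel.E is None:
            raise ValueError("panel must have expected counts (run expected_counts)")
        if graph.n_areas != panel.n_areas:
            raise ValueError("graph and panel disagree on the number of areas")
        n, T = panel.n_areas, panel.n_years
        needs_rw2 = "gamma" in spec.components or spec.interaction in ("II", "IV")
        if needs_rw2 and T < 3:
            raise ValueError("RW2 terms need at least 3 years")
        self.panel = panel
        self.graph = graph
        self.spec = spec
        self.n, self.T = n, T
        # area-major flattening: cell (i, t) at index i*T + t
        self.y = panel.Y.astype(float).ravel()
        self.E = panel.E.astype(float).ravel()
        self.area_of_cell = np.repeat(np.arange(n), T)
        self.year_of_cell = np.tile(np.arange(T), n)
        self.blocks: dict[str, _Block] = {}
        if "U" in spec.components:
            self.blocks["U"] = _Block("U", "area", n, n, None, np.ones(n))
        if "V" in spec.components:
            from .areal_graph import icar_structure
            icar = icar_structure(graph, scale=spec.icar_scaled)
            self.blocks["V"] = _Block("V", "area", n, icar.rank,
                                      icar.range_basis(), icar.nonzero_eigenvalues())
        if "gamma" in spec.components:
            from .areal_graph import rw2_structure
            rw2 = rw2_structure(T)
            self.blocks["gamma"] = _Block("gamma", "year", T, rw2.rank,
                                          rw2.range_basis(), rw2.nonzero_eigenvalues())
        if "phi" in spec.components:
            self.blocks["phi"] = _Block("phi", "year", T, T, None, np.ones(T))
        if spec.interaction != "none":
            if spec.interaction == "I":
                self.blocks["delta"] = _Block("delta", "cell", n * T, n * T,
                                              None, np.ones(n * T))
            else:
                Ra, Rb = interaction_factors(spec.interaction, graph, T,
                                             icar_scaled=spec.icar_scaled)
                Pa, Pb = Ra.range_basis(), Rb.range_basis()
                K = np.kron(Pa, Pb)
                s = np.kron(Ra.nonzero_eigenvalues(), Rb.nonzero_eigenvalues())
                self.blocks["delta"] = _Block("delta", "cell", n * T,
                                              Ra.rank * Rb.rank, K, s,
                                              kron_factors=(Pa, Pb))

    # -- per-cell expansion of a family's full-space vector -------------
    def spread(self, block: _Block, x_full: np.ndarray) -> np.ndarray:
        if block.kind == "area":
            return x_full[self.area_of_cell]
        if block.kind == "year":
            return x_full[self.year_of_cell]
        return x_full

    # -- reduction of a per-cell vector onto a family's index set -------
    def collapse(self, block: _Block, cellvec: np.ndarray) -> np.ndarray:
        if block.kind == "area":
            return np.bincount(self.area_of_cell, weights=cellvec, minlength=self.n)
        if block.kind == "year":
            return np.bincount(self.year_of_cell, weights=cellvec, minlength=self.T)
        return cellvec

    @property
    def n_cells(self) -> int:
        return self.n * self.T


def build_model(panel: CountPanel, graph: SpatialGraph, spec: ModelSpec) -> ModelDef:
    """Assemble the linear-predictor layout and prior structures."""
    return ModelDef(panel, graph, spec)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def nb1_loglik(y, mu, r):
    """NB1 log-pmf: mean ``mu``, variance ``r * mu``.

    Gamma-Poisson mixture with shape ``kappa = mu / (r - 1)`` and success
    probability ``1 / r``; collapses to the Poisson log-pmf as r -> 1.
    Vectorized over y/mu.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    if r < 1.0:
        raise ValueError("overdispersion r must be >= 1")
    if r < _POISSON_EDGE:
        return y * np.log(mu) - mu - gammaln(y + 1.0)
    kappa = mu / (r - 1.0)
    return (gammaln(y + kappa) - gammaln(kappa) - gammaln(y + 1.0)
            - kappa * np.log(r) + y * np.log1p(-1.0 / r))


def nb2_loglik(y, mu, r):
    """NB2 log-pmf with size ``1/(r-1)``: variance ``mu + (r-1) mu^2``."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if r < _POISSON_EDGE:
        return y * np.log(mu) - mu - gammaln(y + 1.0)
    size = 1.0 / (r - 1.0)
    return (gammaln(y + size) - gammaln(size) - gammaln(y + 1.0)
            + size * np.log(size / (size + mu)) + y * np.log(mu / (size + mu)))


def _loglik_eta(model: ModelDef, eta: np.ndarray, r: float) -> float:
    mu = model.E * np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    if model.spec.likelihood == "poisson" or r < _POISSON_EDGE:
        ll = model.y * np.log(mu) - mu - gammaln(model.y + 1.0)
    elif model.spec.nb_variant == "nb2":
        ll = nb2_loglik(model.y, mu, r)
    else:
        ll = nb1_loglik(model.y, mu, r)
    return float(np.sum(ll))


def _pointwise_loglik(model: ModelDef, eta: np.ndarray, r: float) -> np.ndarray:
    mu = model.E * np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    if model.spec.likelihood == "poisson" or r < _POISSON_EDGE:
        return model.y * np.log(mu) - mu - gammaln(model.y + 1.0)
    if model.spec.nb_variant == "nb2":
        return nb2_loglik(model.y, mu, r)
    return nb1_loglik(model.y, mu, r)


def _grad_weight(model: ModelDef, eta: np.ndarray, r: float):
    """Score and positive working weight of the log-likelihood in eta."""
    mu = model.E * np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    y = model.y
    if model.spec.likelihood == "poisson" or r < _POISSON_EDGE:
        return y - mu, np.maximum(mu, 1e-10)
    if model.spec.nb_variant == "nb2":
        size = 1.0 / (r - 1.0)
        g = (y - mu) * size / (size + mu)
        w = mu * size / (size + mu)
        return g, np.maximum(w, 1e-10)
    kappa = mu / (r - 1.0)
    g = kappa * (digamma(y + kappa) - digamma(kappa) - np.log(r))
    w = mu / r
    return g, np.maximum(w, 1e-10)


# ---------------------------------------------------------------------------
# joint log posterior (the sampler's target; also the oracle surface)
# ---------------------------------------------------------------------------

_LOG_2PI = float(np.log(2.0 * np.pi))


def _gamma_logpdf_on_precision(tau: float, shape: float, rate: float) -> float:
    """Gamma(shape, rate) density of tau expressed in the log-tau variable.

    This is the log-gamma hyperprior on the log precision: the density of
    z = log(tau) when tau ~ Gamma(shape, rate), i.e. the Gamma log-pdf
    plus the Jacobian term log(tau).
    """
    return (shape * np.log(rate) - gammaln(shape)
            + shape * np.log(tau) - rate * tau)


def log_posterior(model: ModelDef, state: LatentState) -> float:
    """Joint log density over (alpha, effects, log-precisions, log(r-1)).

    Intrinsic blocks use rank-adjusted normalizing constants (pseudo-
    determinants over the nonzero structure eigenvalues); states are
    assumed to satisfy their constraint sets.
    """
    spec = model.spec
    eta = np.full(model.n_cells, state.alpha)
    values = {"U": state.U, "V": state.V, "gamma": state.gamma,
              "phi": state.phi, "delta": None}
    if state.delta is not None:
        values["delta"] = np.asarray(state.delta).ravel()
    for name, block in model.blocks.items():
        x = values[name]
        if x is None:
            raise ValueError(f"state missing component {name}")
        eta = eta + model.spread(block, np.asarray(x, dtype=float))
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    lp = _loglik_eta(model, eta, state.r)

    for name, block in model.blocks.items():
        x = np.asarray(values[name], dtype=float)
        tau = state.tau[name]
        xi = block.reduce(x)
        quad = float(np.sum(block.s_diag * xi ** 2))
        lp += 0.5 * block.rank * (np.log(tau) - _LOG_2PI)
        lp += 0.5 * block.log_pdet
        lp += -0.5 * tau * quad
        lp += _gamma_logpdf_on_precision(tau, spec.prior_shape, spec.prior_rate)

    lp += -0.5 * (state.alpha / spec.intercept_sd) ** 2 \
          - np.log(spec.intercept_sd) - 0.5 * _LOG_2PI
    if spec.likelihood == "negbin":
        s = np.log(state.r - 1.0)
        lp += -0.5 * (s / spec.logr_sd) ** 2 - np.log(spec.logr_sd) - 0.5 * _LOG_2PI
    return float(lp)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

class _ChainState:
    """Reduced-coordinate sampler state with a cached linear predictor."""

    def __init__(self, model: ModelDef):
        y, E = model.panel.Y, model.panel.E
        self.alpha = float(np.log(max(y.sum(), 1.0) / E.sum()))
        self.xi = {name: np.zeros(b.rank) for name, b in model.blocks.items()}
        self.tau = {name: 10.0 for name in model.blocks}
        self.r = 2.0 if model.spec.likelihood == "negbin" else 1.0
        self.eta = np.full(model.n_cells, self.alpha)

    def contribution(self, model: ModelDef, name: str) -> np.ndarray:
        b = model.blocks[name]
        return model.spread(b, b.full(self.xi[name]))


def _update_block(model: ModelDef, st: _ChainState, name: str,
                  rng: np.random.Generator) -> bool:
    """IWLS Gaussian-approximation MH update of one latent family."""
    b = model.blocks[name]
    xi0 = st.xi[name]
    contrib0 = model.spread(b, b.full(xi0))
    base = st.eta - contrib0
    tau = st.tau[name]

    def proposal(xi_at, eta_at):
        g, w = _grad_weight(model, eta_at, st.r)
        gr = model.collapse(b, g)      # B' g in full family space
        wr = model.collapse(b, w)
        if b.K is None:
            prec = tau * b.s_diag + wr
            mean = (gr + wr * xi_at) / prec
            return mean, prec, None
        gK = b.reduce(gr)
        BWB = b.bwb(wr)
        P = BWB + np.diag(tau * b.s_diag)
        L = np.linalg.cholesky(P)
        rhs = gK + BWB @ xi_at
        mean = cho_solve((L, True), rhs)
        return mean, None, L

    def sample_and_logq(mean, prec, L, value=None):
        if L is None:  # diagonal precision
            if value is None:
                value = mean + rng.standard_normal(mean.size) / np.sqrt(prec)
            logq = float(0.5 * np.sum(np.log(prec)) - 0.5 * mean.size * _LOG_2PI
                         - 0.5 * np.sum(prec * (value - mean) ** 2))
        else:
            if value is None:
                z = rng.standard_normal(mean.size)
                value = mean + solve_triangular(L, z, trans="T", lower=True)
            d = L.T @ (value - mean)
            logq = float(np.sum(np.log(np.diag(L))) - 0.5 * mean.size * _LOG_2PI
                         - 0.5 * d @ d)
        return value, logq

    mean0, prec0, L0 = proposal(xi0, st.eta)
    xi1, logq_fwd = sample_and_logq(mean0, prec0, L0)
    contrib1 = model.spread(b, b.full(xi1))
    eta1 = base + contrib1
    mean1, prec1, L1 = proposal(xi1, eta1)
    _, logq_rev = sample_and_logq(mean1, prec1, L1, value=xi0)

    def logtarget(xi, eta):
        return (_loglik_eta(model, eta, st.r)
                - 0.5 * tau * float(np.sum(b.s_diag * xi ** 2)))

    log_acc = (logtarget(xi1, eta1) - logtarget(xi0, st.eta)
               + logq_rev - logq_fwd)
    if np.log(rng.uniform()) < log_acc:
        st.xi[name] = xi1
        st.eta = eta1
        return True
    return False


def _update_alpha(model: ModelDef, st: _ChainState, rng) -> bool:
    g, w = _grad_weight(model, st.eta, st.r)
    tau0 = 1.0 / model.spec.intercept_sd ** 2
    prec = tau0 + float(w.sum())
    mean = (float(g.sum()) + float(w.sum()) * st.alpha) / prec
    a1 = mean + rng.standard_normal() / np.sqrt(prec)
    eta1 = st.eta + (a1 - st.alpha)
    g1, w1 = _grad_weight(model, eta1, st.r)
    prec1 = tau0 + float(w1.sum())
    mean1 = (float(g1.sum()) + float(w1.sum()) * a1) / prec1
    logq_fwd = 0.5 * np.log(prec) - 0.5 * prec * (a1 - mean) ** 2
    logq_rev = 0.5 * np.log(prec1) - 0.5 * prec1 * (st.alpha - mean1) ** 2
    lt1 = _loglik_eta(model, eta1, st.r) - 0.5 * tau0 * a1 ** 2
    lt0 = _loglik_eta(model, st.eta, st.r) - 0.5 * tau0 * st.alpha ** 2
    if np.log(rng.uniform()) < lt1 - lt0 + logq_rev - logq_fwd:
        st.alpha, st.eta = float(a1), eta1
        return True
    return False


def _update_r(model: ModelDef, st: _ChainState, rng, step: float) -> bool:
    s0 = np.log(st.r - 1.0) if st.r > 1.0 else -10.0
    s1 = s0 + step * rng.standard_normal()
    r1 = 1.0 + np.exp(s1)
    sd = model.spec.logr_sd
    lt1 = _loglik_eta(model, st.eta, r1) - 0.5 * (s1 / sd) ** 2
    lt0 = _loglik_eta(model, st.eta, st.r) - 0.5 * (s0 / sd) ** 2
    if np.log(rng.uniform()) < lt1 - lt0:
        st.r = float(r1)
        return True
    return False


def _update_precisions(model: ModelDef, st: _ChainState, rng) -> None:
    a, b0 = model.spec.prior_shape, model.spec.prior_rate
    for name, block in model.blocks.items():
        quad = float(np.sum(block.s_diag * st.xi[name] ** 2))
        st.tau[name] = float(rng.gamma(a + 0.5 * block.rank,
                                       1.0 / (b0 + 0.5 * quad)))


@dataclass
class PosteriorDraws:
    """Thinned posterior draws with per-cell pointwise log-likelihoods."""

    alpha: np.ndarray                 # (D,)
    effects: dict                     # name -> (D, m) full-space draws
    delta: np.ndarray | None          # (D, n, T)
    r: np.ndarray                     # (D,)
    tau: dict                         # name -> (D,)
    loglik: np.ndarray                # (D, n, T)
    chain_id: np.ndarray              # (D,)
    areas: tuple
    years: tuple
    seed: int
    interaction: str
    likelihood: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.alpha.size

    def component(self, name: str) -> np.ndarray:
        if name == "alpha":
            return self.alpha
        if name == "r":
            return self.r
        if name == "delta":
            if self.delta is None:
                raise KeyError("model has no interaction component")
            return self.delta
        if name in self.effects:
            return self.effects[name]
        raise KeyError(f"unknown component {name!r}")

    def save(self, path) -> None:
        payload = {"alpha": self.alpha, "r": self.r, "loglik": self.loglik,
                   "chain_id": self.chain_id,
                   "seed": np.array(self.seed),
                   "areas": np.array([str(a) for a in self.areas]),
                   "years": np.array(self.years),
                   "interaction": np.array(self.interaction),
                   "likelihood": np.array(self.likelihood)}
        for k, v in self.effects.items():
            payload[f"eff_{k}"] = v
        if self.delta is not None:
            payload["delta"] = self.delta
        for k, v in self.tau.items():
            payload[f"tau_{k}"] = v
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        z = np.load(path)
        effects = {k[4:]: z[k] for k in z.files if k.startswith("eff_")}
        tau = {k[4:]: z[k] for k in z.files if k.startswith("tau_")}
        return cls(alpha=z["alpha"],
                   effects=effects,
                   delta=z["delta"] if "delta" in z.files else None,
                   r=z["r"], tau=tau, loglik=z["loglik"],
                   chain_id=z["chain_id"],
                   areas=tuple(z["areas"].tolist()),
                   years=tuple(int(t) for t in z["years"]),
                   seed=int(z["seed"]),
                   interaction=str(z["interaction"]),
                   likelihood=str(z["likelihood"]))


def fit_mcmc(model: ModelDef, chains: int = 2, iterations: int = 3000,
             burn_in: int = 1000, thin: int = 2, seed: int = 0,
             compute_diagnostics: bool = True) -> PosteriorDraws:
    """Run the blocked Metropolis-within-Gibbs sampler.

    ``iterations`` counts total sweeps per chain; draws are retained after
    ``burn_in`` every ``thin`` sweeps. The random-walk step for log(r-1)
    adapts toward ~40% acceptance during burn-in only, so chains remain
    Markovian over the retained draws and runs are reproducible by seed.
    """
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    if chains < 1:
        raise ValueError("need at least one chain")
    master = np.random.SeedSequence(seed)
    chain_seeds = master.spawn(chains)
    keep_per_chain = (iterations - burn_in) // thin

    n, T = model.n, model.T
    D = keep_per_chain * chains
    alpha = np.empty(D)
    r = np.empty(D)
    chain_id = np.empty(D, dtype=int)
    loglik = np.empty((D, n, T))
    effects = {name: np.empty((D, b.m)) for name, b in model.blocks.items()
               if name != "delta"}
    delta = (np.empty((D, n, T)) if "delta" in model.blocks else None)
    tau = {name: np.empty(D) for name in model.blocks}

    pos = 0
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        st = _ChainState(model)
        step_r = 0.3
        acc_r = 0
        for it in range(iterations):
            _update_alpha(model, st, rng)
            for name in model.blocks:
                _update_block(model, st, name, rng)
            if model.spec.likelihood == "negbin":
                if _update_r(model, st, rng, step_r):
                    acc_r += 1
                if it < burn_in and (it + 1) % 50 == 0:
                    rate = acc_r / 50.0
                    step_r *= np.exp(0.5 * (rate - 0.4))
                    acc_r = 0
            _update_precisions(model, st, rng)
            if not np.isfinite(st.eta).all():
                raise FloatingPointError(
                    f"sampler diverged at chain {c} iteration {it}: "
                    f"alpha={st.alpha}, r={st.r}, tau={st.tau}")
            if it >= burn_in and (it - burn_in) % thin == 0 and pos < D:
                alpha[pos] = st.alpha
                r[pos] = st.r
                chain_id[pos] = c
                for name, b in model.blocks.items():
                    x = b.full(st.xi[name])
                    if name == "delta":
                        delta[pos] = x.reshape(n, T)
                    else:
                        effects[name][pos] = x
                    tau[name][pos] = st.tau[name]
                loglik[pos] = _pointwise_loglik(model, st.eta, st.r).reshape(n, T)
                pos += 1

    draws = PosteriorDraws(alpha=alpha, effects=effects, delta=delta, r=r,
                           tau=tau, loglik=loglik, chain_id=chain_id,
                           areas=model.panel.areas, years=model.panel.years,
                           seed=seed, interaction=model.spec.interaction,
                           likelihood=model.spec.likelihood)
    if compute_diagnostics and chains >= 2 and keep_per_chain >= 4:
        draws.diagnostics = _diagnostics(draws, chains, keep_per_chain)
    return draws


def _diagnostics(draws: PosteriorDraws, chains: int, per_chain: int) -> dict:
    """Split R-hat and bulk effective sample size for the scalar series."""
    import arviz as az

    series = {"alpha": draws.alpha, "r": draws.r}
    for name, t in draws.tau.items():
        series[f"tau_{name}"] = t
    out = {}
    for k, v in series.items():
        mat = v.reshape(chains, per_chain)
        out[k] = {"rhat": float(az.rhat(mat)), "ess": float(az.ess(mat))}
    return out


def posterior_mean_state(draws: PosteriorDraws, model: ModelDef) -> LatentState:
    """Posterior-mean plug-in state (used by the classic DIC pD)."""
    eff = {k: v.mean(axis=0) for k, v in draws.effects.items()}
    return LatentState(
        alpha=float(draws.alpha.mean()),
        U=eff.get("U"), V=eff.get("V"),
        gamma=eff.get("gamma"), phi=eff.get("phi"),
        delta=draws.delta.mean(axis=0) if draws.delta is not None else None,
        r=float(draws.r.mean()),
        tau={k: float(v.mean()) for k, v in draws.tau.items()},
    )


def linear_predictor(model: ModelDef, state: LatentState) -> np.ndarray:
    """Per-cell log relative risk implied by a latent state (flat, area-major)."""
    eta = np.full(model.n_cells, state.alpha)
    mapping = {"U": state.U, "V": state.V, "gamma": state.gamma, "phi": state.phi,
               "delta": None if state.delta is None else np.asarray(state.delta).ravel()}
    for name, block in model.blocks.items():
        eta = eta + model.spread(block, np.asarray(mapping[name], dtype=float))
    return eta


def _kde_mode(x: np.ndarray) -> float:
    from scipy.stats import gaussian_kde

    if np.allclose(x, x[0]):
        return float(x[0])
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def posterior_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Mean, SD, equal-tailed 95% interval and KDE mode per scalar.

    Variance components are reported as 1/precision per family; the
    overdispersion r appears for negative-binomial fits.
    """
    if draws.n_draws < 100:
        raise ValueError("need at least 100 retained draws to summarize")
    rows = {}

    def add(name, x):
        lo, hi = np.quantile(x, [0.025, 0.975])
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        rows[name] = {"mean": float(np.mean(x)), "sd": sd,
                      "ci_low": float(lo), "ci_high": float(hi),
                      "mode": _kde_mode(np.asarray(x, dtype=float))}

    add("intercept", draws.alpha)
    if draws.likelihood == "negbin":
        add("overdispersion_r", draws.r)
    for name, t in draws.tau.items():
        add(f"var_{name}", 1.0 / t)
    return pd.DataFrame.from_dict(rows, orient="index")
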