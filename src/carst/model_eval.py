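"""Model comparison, risk surfaces, exceedance mapping and one-year-ahead
prediction.

DIC uses the classic Spiegelhalter form (pD = mean deviance minus deviance
at the posterior-mean state; a half-variance alternative is available by
flag). WAIC follows Watanabe/Gelman: lppd by log-mean-exp of the pointwise
likelihood over draws, pW as the sum of pointwise variances.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp, polygamma

from .rates_smr import CountPanel, smr
from .st_model import (
    ModelDef,
    PosteriorDraws,
    _pointwise_loglik,
    linear_predictor,
    posterior_mean_state,
)

__all__ = [
    "dic",
    "waic",
    "variance_fractions",
    "exceedance_prob",
    "bin_relative_risk",
    "fitted_vs_observed",
    "predict_year",
    "relative_risk_surface",
    "compare_models",
]

#: relative-risk bin edges (left-closed) and their map legend labels
RISK_BIN_EDGES = (0.5, 0.95, 1.05, 1.5)
RISK_BIN_LABELS = (
    "<0.50",
    "0.50-0.95",
    "0.95-1.05",
    "1.05-1.50",
    ">=1.50",
)


def dic(draws: PosteriorDraws, model: ModelDef, half_variance: bool = False):
    """Deviance information criterion and effective parameter count.

    Returns ``(DIC, pD)`` with ``D = -2 loglik``; pD defaults to
    ``mean(D) - D(posterior-mean state)``.
    """
    dev = -2.0 * draws.loglik.reshape(draws.n_draws, -1).sum(axis=1)
    if not np.all(np.isfinite(dev)):
        raise ValueError("non-finite deviance among draws")
    mean_dev = float(dev.mean())
    if half_variance:
        pd_ = 0.5 * float(dev.var(ddof=1)) if dev.size > 1 else 0.0
    else:
        state = posterior_mean_state(draws, model)
        eta_hat = linear_predictor(model, state)
        dev_hat = -2.0 * float(_pointwise_loglik(model, eta_hat, state.r).sum())
        pd_ = mean_dev - dev_hat
    return mean_dev + pd_, pd_


def waic(draws: PosteriorDraws):
    """Widely applicable information criterion. Returns ``(WAIC, pW)``."""
    ll = draws.loglik.reshape(draws.n_draws, -1)  # (D, cells)
    D = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(D)))
    pw = float(np.sum(ll.var(axis=0, ddof=1)))
    return -2.0 * (lppd - pw), pw


def variance_fractions(draws: PosteriorDraws) -> pd.Series:
    """Share of total variability attributed to each random-effect family.

    Convention: the empirical variance of each family's posterior-mean
    effect values over its index set; the overdispersion contribution is
    the mean per-cell variance of the latent log-gamma mixing noise,
    ``trigamma(kappa_it)`` at the posterior means. Fractions sum to one.
    """
    contrib = {}
    for name, e in draws.effects.items():
        contrib[name] = float(np.var(e.mean(axis=0)))
    if draws.delta is not None:
        contrib["delta"] = float(np.var(draws.delta.mean(axis=0)))
    if draws.likelihood == "negbin":
        r_hat = float(draws.r.mean())
        if r_hat > 1.0 + 1e-8:
            # posterior-mean per-cell mean on the count scale
            mu_hat = np.exp(_mean_eta(draws))
            kappa = mu_hat / (r_hat - 1.0)
            contrib["overdispersion"] = float(np.mean(polygamma(1, kappa)))
        else:
            contrib["overdispersion"] = 0.0
    total = sum(contrib.values())
    if total == 0:
        raise ValueError("all variance contributions are zero")
    return pd.Series({k: v / total for k, v in contrib.items()}, name="fraction")


def _mean_eta(draws: PosteriorDraws) -> np.ndarray:
    """Posterior-mean log relative risk per cell, times E -> mean count.

    Reconstructed from the stored draws (alpha + effects), flat area-major.
    Note: used only for the overdispersion convention; requires no model.
    """
    n, T = len(draws.areas), len(draws.years)
    eta = np.full(n * T, float(draws.alpha.mean()))
    a_of = np.repeat(np.arange(n), T)
    t_of = np.tile(np.arange(T), n)
    for name, e in draws.effects.items():
        m = e.mean(axis=0)
        if m.size == n:
            eta += m[a_of]
        else:
            eta += m[t_of]
    if draws.delta is not None:
        eta += draws.delta.mean(axis=0).ravel()
    return eta


def exceedance_prob(draws: PosteriorDraws, component: str = "delta",
                    threshold: float = 0.0):
    """Posterior exceedance probabilities per element of a component.

    Returns ``(probs, bands)`` where probs is the fraction of draws above
    the threshold and bands classifies each element into ``"<0.2"``,
    ``"0.2-0.8"`` or ``">0.8"`` following common mapping cutoffs.
    """
    x = draws.component(component)
    probs = (x > threshold).mean(axis=0)
    flat = np.asarray(probs).ravel()
    bands = np.where(flat > 0.8, ">0.8", np.where(flat < 0.2, "<0.2", "0.2-0.8"))
    return probs, bands.reshape(np.shape(probs))


def bin_relative_risk(theta_hat) -> np.ndarray:
    """Left-closed risk bins: [0,0.5), [0.5,0.95), [0.95,1.05), [1.05,1.5), [1.5,inf)."""
    theta = np.asarray(theta_hat, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("relative risks must be positive")
    idx = np.digitize(theta, RISK_BIN_EDGES, right=False)
    return np.asarray(RISK_BIN_LABELS, dtype=object)[idx]


def relative_risk_surface(draws: PosteriorDraws) -> np.ndarray:
    """Posterior mean relative risk theta per cell, shape (n, T)."""
    n, T = len(draws.areas), len(draws.years)
    eta = np.full((draws.n_draws, n * T), draws.alpha[:, None])
    a_of = np.repeat(np.arange(n), T)
    t_of = np.tile(np.arange(T), n)
    for name, e in draws.effects.items():
        eta += e[:, a_of] if e.shape[1] == n else e[:, t_of]
    if draws.delta is not None:
        eta += draws.delta.reshape(draws.n_draws, -1)
    return np.exp(eta).mean(axis=0).reshape(n, T)


def fitted_vs_observed(draws: PosteriorDraws, panel: CountPanel) -> dict:
    """Pair observed SMRs with posterior fitted relative risks per cell.

    Returns a dict with the cell table, Pearson correlation and the
    calibration slope of a least-squares line observed ~ fitted.
    """
    theta_hat = relative_risk_surface(draws)
    obs = smr(panel)
    table = pd.DataFrame({
        "area": np.repeat(panel.areas, panel.n_years),
        "year": np.tile(panel.years, panel.n_areas),
        "observed_smr": obs.ravel(),
        "fitted_theta": theta_hat.ravel(),
    })
    x, y = theta_hat.ravel(), obs.ravel()
    corr = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.polyfit(x, y, 1)[0])
    return {"table": table, "correlation": corr, "slope": slope}


def predict_year(draws: PosteriorDraws, E_new: np.ndarray, seed: int = 0,
                 policy: str = "auto") -> dict:
    """Posterior predictive counts and risks for one out-of-sample year.

    For each retained draw the temporal effects are continued one step:
    gamma by its RW2 conditional (``2*gamma_T - gamma_{T-1}`` plus an
    innovation at the drawn precision), phi by a fresh iid draw. The
    interaction continues per ``policy``: ``"rw2"`` carries each area's
    series forward by the RW2 conditional (default for types II/IV),
    ``"iid"`` draws fresh zero-mean values (default for types I/III and
    no-interaction fits), ``"freeze"`` plugs in the last year's posterior
    values unchanged. Counts are then sampled from the observation model.

    Returns per-area predictive count draws, relative-risk draws, and the
    total-count predictive distribution.
    """
    E_new = np.asarray(E_new, dtype=float)
    n = len(draws.areas)
    if E_new.shape != (n,):
        raise ValueError(f"E_new must have length {n}")
    if np.any(E_new <= 0):
        raise ValueError("E_new must be positive")
    if policy not in ("auto", "rw2", "iid", "freeze"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "auto":
        policy = "rw2" if draws.interaction in ("II", "IV") else "iid"

    rng = np.random.default_rng(seed)
    D = draws.n_draws
    eta = np.tile(draws.alpha[:, None], (1, n))
    for name in ("U", "V"):
        if name in draws.effects:
            eta += draws.effects[name]
    if "gamma" in draws.effects:
        g = draws.effects["gamma"]
        sd = 1.0 / np.sqrt(draws.tau["gamma"])
        g_next = 2.0 * g[:, -1] - g[:, -2] + sd * rng.standard_normal(D)
        eta += g_next[:, None]
    if "phi" in draws.effects:
        sd = 1.0 / np.sqrt(draws.tau["phi"])
        eta += (sd * rng.standard_normal(D))[:, None]
    if draws.delta is not None:
        sd = (1.0 / np.sqrt(draws.tau["delta"]))[:, None]
        last = draws.delta[:, :, -1]
        if policy == "freeze":
            d_next = last
        elif policy == "rw2" and draws.delta.shape[2] >= 2:
            d_next = (2.0 * last - draws.delta[:, :, -2]
                      + sd * rng.standard_normal((D, n)))
        else:
            d_next = sd * rng.standard_normal((D, n))
        eta += d_next

    theta = np.exp(np.clip(eta, -40, 40))
    mu = E_new[None, :] * theta
    if draws.likelihood == "poisson":
        counts = rng.poisson(mu)
    else:
        r = draws.r[:, None]
        poisson_like = r < 1.0 + 1e-8
        kappa = np.where(poisson_like, 1.0, mu / np.maximum(r - 1.0, 1e-12))
        lam = np.where(poisson_like, mu,
                       rng.gamma(kappa, np.maximum(r - 1.0, 1e-12)))
        counts = rng.poisson(lam)
    return {
        "count_draws": counts,
        "theta_draws": theta,
        "total_draws": counts.sum(axis=1),
        "total_mean": float(counts.sum(axis=1).mean()),
        "policy": policy,
    }


def compare_models(panel: CountPanel, graph, base_spec, interactions=None,
                   chains: int = 2, iterations: int = 1500, burn_in: int = 500,
                   thin: int = 2, seed: int = 0) -> pd.DataFrame:
    """Fit the five interaction specifications and tabulate DIC/pD/WAIC/pW."""
    from dataclasses import replace

    from .st_model import build_model, fit_mcmc

    if interactions is None:
        interactions = ("none", "I", "II", "III", "IV")
    rows = {}
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(interactions))]
    for itype, sd in zip(interactions, seeds):
        spec = replace(base_spec, interaction=itype)
        model = build_model(panel, graph, spec)
        draws = fit_mcmc(model, chains=chains, iterations=iterations,
                         burn_in=burn_in, thin=thin, seed=sd,
                         compute_diagnostics=False)
        d, pd_ = dic(draws, model)
        w, pw = waic(draws)
        rows[itype] = {"DIC": d, "pD": pd_, "WAIC": w, "pW": pw}
    return pd.DataFrame.from_dict(rows, orient="index")[["DIC", "pD", "WAIC", "pW"]]
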