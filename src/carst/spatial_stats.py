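"""Global Moran's I and local Moran (LISA) with permutation inference.

Both statistics are computed from a contiguity-based spatial weight
matrix. Inference is by Monte-Carlo relabeling: the global test permutes
the whole value vector (one-sided, positive-autocorrelation alternative);
the local statistics use conditional permutation, holding each area's own
value fixed while permuting the remaining values among its neighbors.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix

from .areal_graph import SpatialGraph

__all__ = [
    "WeightMatrix",
    "MoranResult",
    "LISAResult",
    "build_weights",
    "morans_i",
    "moran_permutation_test",
    "local_moran",
]

QUADRANTS = ("High-High", "Low-Low", "Low-High", "High-Low", "Non-significant")


@dataclass(frozen=True)
class WeightMatrix:
    """Spatial weights derived from a contiguity graph.

    ``style`` is "binary" (0/1) or "row_standardized" (rows with at least
    one neighbor sum to one). Island rows are all zero.
    """

    graph: SpatialGraph
    style: str
    weights: csr_matrix

    @property
    def n(self) -> int:
        return self.graph.n_areas

    @property
    def s0(self) -> float:
        """Sum of all weights."""
        return float(self.weights.sum())

    def dense(self) -> np.ndarray:
        return self.weights.toarray()


def build_weights(graph: SpatialGraph, style: str = "row_standardized") -> WeightMatrix:
    if style not in ("binary", "row_standardized"):
        raise ValueError(f"unknown weight style {style!r}")
    W = graph.adjacency_sparse().astype(float).tolil()
    if style == "row_standardized":
        for i in range(graph.n_areas):
            row = W.rows[i]
            if row:
                k = len(row)
                W.data[i] = [1.0 / k] * k
    isl = graph.islands()
    if isl:
        warnings.warn(f"weight matrix has island rows (all zero): {isl}", stacklevel=2)
    return WeightMatrix(graph=graph, style=style, weights=W.tocsr())


def _center(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    z = x - x.mean()
    if np.allclose(z, 0.0):
        raise ValueError("constant input: Moran's I undefined")
    return z


def morans_i(x: np.ndarray, w: WeightMatrix) -> float:
    """Global Moran's I: ``(n / S0) * (z' W z) / (z' z)`` with centered z."""
    z = _center(x)
    if z.size != w.n:
        raise ValueError("length of x must match number of areas")
    num = float(z @ (w.weights @ z))
    return (w.n / w.s0) * num / float(z @ z)


@dataclass(frozen=True)
class MoranResult:
    statistic: float
    n_perm: int
    pseudo_p: float
    seed: int
    permuted: np.ndarray = None

    def __post_init__(self):
        if not (0.0 < self.pseudo_p <= 1.0):
            raise ValueError("pseudo p-value out of (0, 1]")


def moran_permutation_test(x, w: WeightMatrix, n_perm: int = 999,
                           seed: int = 0) -> MoranResult:
    """One-sided Monte-Carlo test of positive spatial autocorrelation.

    pseudo_p = (1 + #{permuted I >= observed I}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    obs = morans_i(x, w)
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    sims = np.empty(n_perm)
    for k in range(n_perm):
        sims[k] = morans_i(rng.permutation(x), w)
    p = (1.0 + np.sum(sims >= obs)) / (n_perm + 1.0)
    return MoranResult(statistic=obs, n_perm=n_perm, pseudo_p=float(p),
                       seed=seed, permuted=sims)


@dataclass(frozen=True)
class LISAResult:
    statistic: np.ndarray   # local I per area
    pseudo_p: np.ndarray
    quadrant: tuple          # label per area
    alpha: float
    n_perm: int
    seed: int


def local_moran(x, w: WeightMatrix, n_perm: int = 999, seed: int = 0,
                alpha: float = 0.05) -> LISAResult:
    """Local Moran statistics with conditional permutation p-values.

    ``I_i = (n / sum z^2) * z_i * lag_i`` where ``lag_i`` is the weighted
    average (or sum, for binary weights) of neighbor deviations. For each
    area the neighbor values are resampled without replacement from the
    remaining n-1 observations; the pseudo p-value is one-sided in the
    direction of the observed local statistic. Quadrant labels come from
    the signs of (z_i, lag_i); areas with p > alpha are Non-significant.
    """
    z = _center(x)
    n = w.n
    if z.size != n:
        raise ValueError("length of x must match number of areas")
    denom = float(z @ z)
    lag = w.weights @ z
    I_obs = (n / denom) * z * lag

    master = np.random.default_rng(seed)
    seeds = master.spawn(n)
    W = w.weights
    pseudo_p = np.ones(n)
    for i in range(n):
        row = W.getrow(i)
        nbr_w = row.data
        if nbr_w.size == 0:
            pseudo_p[i] = 1.0
            continue
        rng = np.random.default_rng(seeds[i])
        others = np.delete(z, i)
        k = nbr_w.size
        # draw n_perm neighbor subsets of size k without replacement
        draws = np.empty((n_perm, k))
        for p_ in range(n_perm):
            take = rng.choice(others.size, size=k, replace=False)
            draws[p_] = others[take]
        sims = (n / denom) * z[i] * (draws @ nbr_w)
        if I_obs[i] >= 0:
            extreme = np.sum(sims >= I_obs[i])
        else:
            extreme = np.sum(sims <= I_obs[i])
        pseudo_p[i] = (1.0 + extreme) / (n_perm + 1.0)

    labels = []
    for i in range(n):
        if pseudo_p[i] > alpha:
            labels.append("Non-significant")
        elif z[i] > 0 and lag[i] > 0:
            labels.append("High-High")
        elif z[i] < 0 and lag[i] < 0:
            labels.append("Low-Low")
        elif z[i] < 0:
            labels.append("Low-High")
        else:
            labels.append("High-Low")
    return LISAResult(statistic=I_obs, pseudo_p=pseudo_p, quadrant=tuple(labels),
                      alpha=alpha, n_perm=n_perm, seed=seed)
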