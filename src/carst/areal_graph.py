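"""Spatial contiguity graphs and intrinsic Gaussian prior structures.

This module provides the substrate for every spatially or temporally
structured random effect in the package: undirected area adjacency
(:class:`SpatialGraph`), the (generally rank-deficient) prior precision
structures built on it — intrinsic CAR over areas, second-order random
walk over time, and their Kronecker products for the four Knorr-Held
space-time interaction types — and the linear identifiability constraints
under which those improper priors become proper.

All interaction-level vectors use *area-major* ordering: the cell for
area ``i`` at time ``t`` sits at flat index ``i * T + t``.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csgraph, csr_matrix

__all__ = [
    "SpatialGraph",
    "StructureMatrix",
    "INTERACTION_TYPES",
    "graph_from_edges",
    "graph_from_polygons",
    "icar_structure",
    "rw2_structure",
    "interaction_structure",
    "constraint_basis",
    "read_edge_list",
    "read_gal",
]

#: valid Knorr-Held interaction codes
INTERACTION_TYPES = ("none", "I", "II", "III", "IV")


def _rank_tol(singular_values: np.ndarray, dim: int) -> float:
    """Zero threshold for rank decisions: max_dim * eps * largest value."""
    if singular_values.size == 0:
        return 0.0
    return dim * np.finfo(float).eps * float(np.max(np.abs(singular_values)))


@dataclass(frozen=True)
class SpatialGraph:
    """Undirected contiguity graph over ``n_areas`` areas.

    Edges are stored as a frozenset of ``(i, j)`` pairs with ``i < j``;
    construction through :func:`graph_from_edges` guarantees symmetry,
    no self-loops and indices in ``[0, n_areas)``.
    """

    n_areas: int
    edges: frozenset
    labels: tuple | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbor_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_areas, dtype=int)
        for i, j in self.edges:
            counts[i] += 1
            counts[j] += 1
        return counts

    def neighbors(self, i: int) -> list:
        out = []
        for a, b in self.edges:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix."""
        A = np.zeros((self.n_areas, self.n_areas))
        for i, j in self.edges:
            A[i, j] = A[j, i] = 1.0
        return A

    def adjacency_sparse(self) -> csr_matrix:
        if not self.edges:
            return csr_matrix((self.n_areas, self.n_areas))
        rows, cols = [], []
        for i, j in self.edges:
            rows += [i, j]
            cols += [j, i]
        data = np.ones(len(rows))
        return csr_matrix((data, (rows, cols)), shape=(self.n_areas, self.n_areas))

    def components(self) -> np.ndarray:
        """Connected-component label per area."""
        _, labels = csgraph.connected_components(self.adjacency_sparse(), directed=False)
        return labels

    def n_components(self) -> int:
        return int(self.components().max()) + 1 if self.n_areas else 0

    def islands(self) -> list:
        counts = self.neighbor_counts()
        return [int(i) for i in np.flatnonzero(counts == 0)]


def graph_from_edges(edge_list: Iterable, n_areas: int, labels: Sequence | None = None) -> SpatialGraph:
    """Build a :class:`SpatialGraph` from (i, j) index pairs.

    Duplicate and reversed pairs collapse to a single undirected edge.

    Raises
    ------
    ValueError
        on self-loops or indices outside ``[0, n_areas)``.
    """
    if n_areas < 1:
        raise ValueError("n_areas must be positive")
    edges = set()
    for i, j in edge_list:
        i, j = int(i), int(j)
        if i == j:
            raise ValueError(f"self-loop ({i},{i}) is not a valid contiguity edge")
        if not (0 <= i < n_areas) or not (0 <= j < n_areas):
            raise ValueError(f"edge ({i},{j}) has an id out of range [0, {n_areas})")
        edges.add((min(i, j), max(i, j)))
    lab = tuple(labels) if labels is not None else None
    if lab is not None and len(lab) != n_areas:
        raise ValueError("labels length must equal n_areas")
    return SpatialGraph(n_areas=n_areas, edges=frozenset(edges), labels=lab)


def graph_from_polygons(collection, id_property: str | None = None) -> SpatialGraph:
    """Queen contiguity graph from a GeoJSON FeatureCollection.

    Two areas are neighbors when their polygons share at least one
    boundary point (queen rule). ``collection`` may be a mapping, a JSON
    string, or a path to a GeoJSON file. Feature identifiers come from
    ``properties[id_property]`` when given, else the feature ``id``, else
    positional order. Islands (zero neighbors) are allowed but reported
    through a warning.
    """
    from shapely.geometry import shape
    from shapely.strtree import STRtree

    if isinstance(collection, (str, Path)):
        text = Path(collection).read_text() if Path(str(collection)).exists() else str(collection)
        collection = json.loads(text)
    feats = collection["features"]
    geoms, ids = [], []
    for k, f in enumerate(feats):
        if id_property is not None:
            fid = f["properties"][id_property]
        else:
            fid = f.get("id", k)
        ids.append(fid)
        geom = shape(f["geometry"])
        if not geom.is_valid:
            raise ValueError(f"invalid geometry for feature {fid!r}")
        geoms.append(geom)
    if len(set(map(str, ids))) != len(ids):
        raise ValueError("duplicate feature identifiers")

    tree = STRtree(geoms)
    edges = set()
    for i, g in enumerate(geoms):
        for j in tree.query(g, predicate="intersects"):
            j = int(j)
            if j > i:
                edges.add((i, j))
    graph = SpatialGraph(n_areas=len(geoms), edges=frozenset(edges),
                         labels=tuple(str(x) for x in ids))
    isl = graph.islands()
    if isl:
        names = [graph.labels[i] for i in isl]
        warnings.warn(f"island areas with no neighbors: {names}", stacklevel=2)
    return graph


@dataclass
class StructureMatrix:
    """Symmetric non-negative-definite prior precision structure.

    ``entries`` is the structure matrix R (the actual prior precision is
    ``tau * R``); ``rank`` its numerical rank; ``null_basis`` an
    orthonormal ``(order, order - rank)`` basis of its null space.
    ``eigenvalues``/``eigenvectors`` of R are kept for spectral sampling
    and pseudo-determinants.
    """

    entries: np.ndarray
    rank: int
    null_basis: np.ndarray
    eigenvalues: np.ndarray = field(repr=False, default=None)
    eigenvectors: np.ndarray = field(repr=False, default=None)

    @property
    def order(self) -> int:
        return self.entries.shape[0]

    @property
    def null_dim(self) -> int:
        return self.order - self.rank

    def range_basis(self) -> np.ndarray:
        """Orthonormal basis of the row space (constraint-satisfying subspace)."""
        if self.eigenvectors is None:
            self._decompose()
        tol = _rank_tol(self.eigenvalues, self.order)
        return self.eigenvectors[:, self.eigenvalues > tol]

    def nonzero_eigenvalues(self) -> np.ndarray:
        if self.eigenvectors is None:
            self._decompose()
        tol = _rank_tol(self.eigenvalues, self.order)
        return self.eigenvalues[self.eigenvalues > tol]

    def log_pseudo_det(self) -> float:
        return float(np.sum(np.log(self.nonzero_eigenvalues())))

    def marginal_variances(self) -> np.ndarray:
        """Diagonal of the pseudo-inverse (per-coordinate prior variance
        at unit precision), restricted to the nonzero eigendirections."""
        P = self.range_basis()
        vals = self.nonzero_eigenvalues()
        return (P ** 2 / vals[None, :]).sum(axis=1)

    def quadratic_form(self, x: np.ndarray) -> float:
        return float(x @ self.entries @ x)

    def _decompose(self) -> None:
        vals, vecs = np.linalg.eigh(self.entries)
        self.eigenvalues, self.eigenvectors = vals, vecs

    @classmethod
    def from_matrix(cls, entries: np.ndarray) -> "StructureMatrix":
        entries = np.asarray(entries, dtype=float)
        entries = 0.5 * (entries + entries.T)
        vals, vecs = np.linalg.eigh(entries)
        tol = _rank_tol(vals, entries.shape[0])
        nz = vals > tol
        return cls(entries=entries, rank=int(nz.sum()),
                   null_basis=vecs[:, ~nz], eigenvalues=vals, eigenvectors=vecs)


def icar_structure(graph: SpatialGraph, scale: bool = False) -> StructureMatrix:
    """Intrinsic CAR structure: graph Laplacian ``diag(degree) - adjacency``.

    For a connected graph the rank is ``n - 1`` with the constant vector in
    the null space; disconnected graphs contribute one null vector per
    component. With ``scale=True`` each connected component's block is
    rescaled so the geometric mean of the marginal variances (diagonal of
    the pseudo-inverse) on that component equals one. Islands keep a zero
    row (their effect defers entirely to the unstructured term).
    """
    if graph.n_areas < 2:
        raise ValueError("ICAR structure needs at least 2 areas")
    A = graph.adjacency()
    R = np.diag(A.sum(axis=1)) - A
    comp = graph.components()
    if scale:
        Rp = np.linalg.pinv(R)
        d = np.diag(Rp)
        for c in np.unique(comp):
            idx = np.flatnonzero(comp == c)
            if idx.size < 2:
                continue  # islands: zero row stays zero
            g = np.exp(np.mean(np.log(d[idx])))
            R[np.ix_(idx, idx)] *= g
    n = graph.n_areas
    n_comp = int(comp.max()) + 1
    # analytic null basis: normalized component indicators
    N = np.zeros((n, n_comp))
    for c in range(n_comp):
        idx = comp == c
        N[idx, c] = 1.0 / np.sqrt(idx.sum())
    vals, vecs = np.linalg.eigh(R)
    return StructureMatrix(entries=R, rank=n - n_comp, null_basis=N,
                           eigenvalues=vals, eigenvectors=vecs)


def rw2_structure(T: int) -> StructureMatrix:
    """Second-order random-walk structure ``D2' D2`` on T time points.

    Rank ``T - 2``; the null space is spanned by the constant and the
    linear-in-time vectors (locally linear trends are unpenalized).
    """
    if T < 3:
        raise ValueError("RW2 needs at least 3 time points")
    D = np.zeros((T - 2, T))
    for k in range(T - 2):
        D[k, k:k + 3] = (1.0, -2.0, 1.0)
    R = D.T @ D
    t = np.arange(T, dtype=float)
    N = np.stack([np.ones(T), t - t.mean()], axis=1)
    N, _ = np.linalg.qr(N)
    vals, vecs = np.linalg.eigh(R)
    return StructureMatrix(entries=R, rank=T - 2, null_basis=N,
                           eigenvalues=vals, eigenvectors=vecs)


def _kron_null_basis(Ra: StructureMatrix, Rb: StructureMatrix) -> np.ndarray:
    """Orthonormal null basis of kron(Ra, Rb) from the factor bases.

    null(A (x) B) = span{ null(A) (x) anything } + span{ range(A) (x) null(B) }.
    """
    na, nb = Ra.order, Rb.order
    blocks = []
    if Ra.null_dim:
        blocks.append(np.kron(Ra.null_basis, np.eye(nb)))
    if Rb.null_dim:
        Pa = Ra.range_basis()
        if Pa.shape[1]:
            blocks.append(np.kron(Pa, Rb.null_basis))
    if not blocks:
        return np.zeros((na * nb, 0))
    return np.hstack(blocks)


def interaction_structure(itype: str, graph: SpatialGraph, T: int) -> StructureMatrix:
    """Knorr-Held interaction prior structure over the n*T cell vector.

    Area-major ordering (cell (i, t) at index ``i*T + t``), so the
    Kronecker products put the spatial factor first:

    - Type I:   I_n (x) I_T         (iid space x iid time, full rank)
    - Type II:  I_n (x) RW2_T       (iid space x structured time)
    - Type III: ICAR_n (x) I_T      (structured space x iid time)
    - Type IV:  ICAR_n (x) RW2_T    (structured space x structured time)
    """
    if itype not in ("I", "II", "III", "IV"):
        raise ValueError(f"unsupported interaction type {itype!r}")
    n = graph.n_areas
    if itype in ("II", "IV") and T < 3:
        raise ValueError("types II and IV need T >= 3 for the RW2 factor")
    eye_n = StructureMatrix(np.eye(n), n, np.zeros((n, 0)),
                            np.ones(n), np.eye(n))
    eye_T = StructureMatrix(np.eye(T), T, np.zeros((T, 0)),
                            np.ones(T), np.eye(T))
    if itype == "I":
        Ra, Rb = eye_n, eye_T
    elif itype == "II":
        Ra, Rb = eye_n, rw2_structure(T)
    elif itype == "III":
        Ra, Rb = icar_structure(graph), eye_T
    else:
        Ra, Rb = icar_structure(graph), rw2_structure(T)
    R = np.kron(Ra.entries, Rb.entries)
    rank = Ra.rank * Rb.rank
    null = _kron_null_basis(Ra, Rb)
    return StructureMatrix(entries=R, rank=rank, null_basis=null)


def interaction_factors(itype: str, graph: SpatialGraph, T: int,
                        icar_scaled: bool = False) -> tuple:
    """The (spatial, temporal) factor structures of an interaction type.

    Used by the model to exploit ``kron`` identities instead of forming
    the full n*T x n*T matrix.
    """
    if itype not in ("I", "II", "III", "IV"):
        raise ValueError(f"unsupported interaction type {itype!r}")
    n = graph.n_areas
    eye_n = StructureMatrix(np.eye(n), n, np.zeros((n, 0)), np.ones(n), np.eye(n))
    eye_T = StructureMatrix(np.eye(T), T, np.zeros((T, 0)), np.ones(T), np.eye(T))
    Ra = icar_structure(graph, scale=icar_scaled) if itype in ("III", "IV") else eye_n
    Rb = rw2_structure(T) if itype in ("II", "IV") else eye_T
    return Ra, Rb


def constraint_basis(itype: str, graph: SpatialGraph, T: int) -> list:
    """Identifiability constraints for the interaction's intrinsic prior.

    Returns an orthonormal, linearly independent list of constraint
    vectors over the n*T cells (area-major): the interaction must be
    orthogonal to each. Type I needs none; Type II removes per-area
    constant and linear-in-time components; Type III removes per-year
    sums within each connected component; Type IV both families (with
    redundant directions dropped). The span equals the null space of the
    corresponding Kronecker structure.
    """
    if itype == "none":
        return []
    if itype not in ("I", "II", "III", "IV"):
        raise ValueError(f"unsupported interaction type {itype!r}")
    if itype == "I":
        return []
    n = graph.n_areas
    t = np.arange(T, dtype=float)
    vectors = []
    if itype in ("II", "IV"):
        for i in range(n):
            v = np.zeros(n * T)
            v[i * T:(i + 1) * T] = 1.0
            vectors.append(v)
            w = np.zeros(n * T)
            w[i * T:(i + 1) * T] = t - t.mean()
            vectors.append(w)
    if itype in ("III", "IV"):
        comp = graph.components()
        for c in np.unique(comp):
            idx = np.flatnonzero(comp == c)
            for tt in range(T):
                v = np.zeros(n * T)
                v[idx * T + tt] = 1.0
                vectors.append(v)
    M = np.stack(vectors, axis=1)
    # drop redundant directions (types IV overlap between families)
    q, s, _ = np.linalg.svd(M, full_matrices=False)
    keep = s > _rank_tol(s, max(M.shape))
    return [q[:, k] for k in range(M.shape[1]) if keep[k]]


def read_edge_list(path) -> list:
    """Whitespace-separated ``id_a id_b`` lines; '#' starts a comment."""
    pairs = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed edge line: {raw!r}")
        pairs.append((parts[0], parts[1]))
    return pairs


def read_gal(path) -> SpatialGraph:
    """GAL-dialect adjacency: header line with n, then per-area blocks.

    Each block is a line ``area_id k`` followed by a line with k neighbor
    ids. Ids may be arbitrary tokens; they are mapped to indices in order
    of first appearance in the header blocks.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    header = lines[0].split()
    n = int(header[0])
    idx = {}
    entries = []  # (id, [neighbor ids])
    k = 1
    while k < len(lines):
        aid, deg = lines[k].split()[0], int(lines[k].split()[1])
        if deg > 0:
            nbrs = lines[k + 1].split()
            if len(nbrs) != deg:
                raise ValueError(f"area {aid}: expected {deg} neighbors, got {len(nbrs)}")
            k += 2
        else:
            nbrs = []
            k += 1
        entries.append((aid, nbrs))
    for aid, _ in entries:
        if aid in idx:
            raise ValueError(f"duplicate area id {aid!r} in GAL file")
        idx[aid] = len(idx)
    if len(idx) != n:
        raise ValueError(f"GAL header says {n} areas, found {len(idx)}")
    edges = []
    for aid, nbrs in entries:
        for b in nbrs:
            if b not in idx:
                raise ValueError(f"unknown neighbor id {b!r}")
            edges.append((idx[aid], idx[b]))
    labels = [aid for aid, _ in entries]
    return graph_from_edges(edges, n, labels=labels)
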