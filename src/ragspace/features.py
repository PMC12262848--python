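"""Persistent-spectral-graph featurization of dual graphs.

Adjacency entries are read as inter-stem distances: the edge {i, j} enters the
filtration at ``d = A_ij`` (so singly-connected pairs appear first and
triply-connected, pseudoknot-like pairs last), giving a nested family of
clique complexes K_1 ⊆ K_2 ⊆ K_3.  At each snapshot the q-th combinatorial
Laplacian is

    L_q = B_{q+1} B_{q+1}ᵀ + B_qᵀ B_q

with B_q the signed boundary matrix from q- to (q-1)-simplices; the number of
zero eigenvalues of L_q is the Betti-q number of the snapshot.

The 19-dimensional descriptor of a topology collects statistics of the L_0
spectra — (sum, smallest nonzero, variance, #zeros) at d=1 and
(sum, smallest nonzero, max, mean, std, variance, #zeros) at d=2 and d=3 —
plus the average hairpin degree ``Avg(Deg) = Σ_i A_ii / 2n``, which restores
the self-loop information the distance filtration ignores.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .dualgraph import DualGraph, InputError, is_valid_dual_graph

__all__ = [
    "FiltrationComplex",
    "SpectrumResult",
    "FEATURE_NAMES",
    "build_filtration",
    "boundary_matrix",
    "persistent_laplacian",
    "spectrum",
    "psg_features",
    "featurize_catalog",
    "PSGFeaturizer",
]

ZERO_TOL = 1e-8

FEATURE_NAMES: tuple[str, ...] = (
    "d1_sum",
    "d1_nonzero_min",
    "d1_variance",
    "d1_zero_count",
    "d2_sum",
    "d2_nonzero_min",
    "d2_max",
    "d2_mean",
    "d2_std",
    "d2_variance",
    "d2_zero_count",
    "d3_sum",
    "d3_nonzero_min",
    "d3_max",
    "d3_mean",
    "d3_std",
    "d3_variance",
    "d3_zero_count",
    "avg_degree",
)


@dataclass(frozen=True)
class FiltrationComplex:
    """Clique complex of the edges present at filtration value ``d``."""

    d: int
    n_vertices: int
    edges: tuple[tuple[int, int], ...]
    triangles: tuple[tuple[int, int, int], ...]
    tetrahedra: tuple[tuple[int, int, int, int], ...]

    def simplices(self, q: int):
        if q == 0:
            return tuple((v,) for v in range(self.n_vertices))
        return {1: self.edges, 2: self.triangles, 3: self.tetrahedra}.get(q, ())


def build_filtration(g: DualGraph, d: int) -> FiltrationComplex:
    """Clique complex at distance-filtration value ``d`` (0 = vertices only).

    An edge {i, j} is present iff ``1 <= A_ij <= d``; self-loops and edge
    multiplicities create no extra simplices.  Triangles and tetrahedra are
    the 3- and 4-cliques of the present edge set.
    """
    if d < 0:
        raise InputError("filtration value must be >= 0")
    off = g.offdiag()
    edges = tuple(
        (i, j)
        for i in range(g.n)
        for j in range(i + 1, g.n)
        if 1 <= off[i, j] <= d
    )
    eset = set(edges)
    adj = [set() for _ in range(g.n)]
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    triangles = tuple(
        (i, j, k)
        for i, j in edges
        for k in sorted(adj[i] & adj[j])
        if k > j
    )
    tetrahedra = tuple(
        t
        for t in combinations(range(g.n), 4)
        if all((a, b) in eset for a, b in combinations(t, 2))
    )
    return FiltrationComplex(d, g.n, edges, triangles, tetrahedra)


def boundary_matrix(K: FiltrationComplex, q: int) -> np.ndarray:
    """Signed boundary matrix B_q mapping q-simplices to (q-1)-simplices.

    Orientation follows ascending vertex indices; B_0 is the empty map.
    Shape is (#(q-1)-simplices, #q-simplices).
    """
    if q <= 0:
        return np.zeros((0, K.n_vertices), dtype=float)
    rows = {s: idx for idx, s in enumerate(K.simplices(q - 1))}
    cols = K.simplices(q)
    B = np.zeros((len(rows), len(cols)), dtype=float)
    for c, simplex in enumerate(cols):
        for drop in range(len(simplex)):
            face = simplex[:drop] + simplex[drop + 1 :]
            B[rows[face], c] = (-1.0) ** drop
    return B


def persistent_laplacian(K: FiltrationComplex, q: int) -> np.ndarray:
    """q-th combinatorial Laplacian of the snapshot ``K`` (0-persistent case).

    Returns an empty (0, 0) matrix when the complex has no q-simplices.
    """
    nq = len(K.simplices(q))
    if nq == 0:
        return np.zeros((0, 0), dtype=float)
    Bq = boundary_matrix(K, q)
    Bq1 = boundary_matrix(K, q + 1)
    L = Bq.T @ Bq
    if Bq1.shape[1]:
        L = L + Bq1 @ Bq1.T
    return L


@dataclass(frozen=True)
class SpectrumResult:
    eigenvalues: np.ndarray
    betti: int


def spectrum(L: np.ndarray, zero_tol: float = ZERO_TOL) -> SpectrumResult:
    """Ascending eigenvalues and kernel dimension (Betti number) of ``L``."""
    L = np.asarray(L, dtype=float)
    if L.size == 0:
        return SpectrumResult(np.zeros(0), 0)
    if not np.allclose(L, L.T):
        raise InputError("Laplacian must be symmetric")
    ev = np.linalg.eigvalsh(L)
    return SpectrumResult(ev, int(np.sum(ev < zero_tol)))


def _spectrum_stats(ev: np.ndarray, zero_tol: float, include_zeros: bool) -> dict:
    zeros = int(np.sum(ev < zero_tol))
    nonzero = ev[ev >= zero_tol]
    pool = ev if include_zeros else nonzero
    if pool.size == 0:
        pool = np.zeros(1)
    return {
        "sum": float(ev.sum()),
        "nonzero_min": float(nonzero.min()) if nonzero.size else 0.0,
        "max": float(pool.max()),
        "mean": float(pool.mean()),
        "std": float(pool.std()),  # population form
        "variance": float(pool.var()),
        "zero_count": float(zeros),
    }


def psg_features(
    g: DualGraph, zero_tol: float = ZERO_TOL, include_zeros: bool = True
) -> dict[str, float]:
    """The ordered 19-feature PSG descriptor of a dual graph.

    ``include_zeros`` controls whether the zero eigenvalues enter the
    mean/std/variance/max statistics (they always enter ``sum`` through the
    trace and are always counted by ``zero_count``).
    """
    if not is_valid_dual_graph(g.A):
        raise InputError("psg_features requires a valid dual graph")
    out: dict[str, float] = {}
    for d in (1, 2, 3):
        K = build_filtration(g, d)
        ev = spectrum(persistent_laplacian(K, 0), zero_tol).eigenvalues
        stats = _spectrum_stats(ev, zero_tol, include_zeros)
        if d == 1:
            keys = ("sum", "nonzero_min", "variance", "zero_count")
        else:
            keys = ("sum", "nonzero_min", "max", "mean", "std", "variance", "zero_count")
        for k in keys:
            out[f"d{d}_{k}"] = stats[k]
    out["avg_degree"] = float(np.trace(g.A)) / (2 * g.n)
    return out


def featurize_catalog(catalog, zero_tol: float = ZERO_TOL, include_zeros: bool = True) -> pd.DataFrame:
    """One 19-feature row per catalog member, indexed by GraphID."""
    rows = {
        str(gid): psg_features(g, zero_tol, include_zeros)
        for gid, g in catalog.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    df.index.name = "id"
    return df


class PSGFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: dual graphs -> 19-feature matrix.

    Accepts a sequence of :class:`DualGraph` (or a catalog) and returns an
    ``(n_graphs, 19)`` float array in the fixed :data:`FEATURE_NAMES` order.
    """

    def __init__(self, zero_tol: float = ZERO_TOL, include_zeros: bool = True):
        self.zero_tol = zero_tol
        self.include_zeros = include_zeros

    def fit(self, X, y=None):
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X) -> np.ndarray:
        graphs = list(X.graphs.values()) if hasattr(X, "graphs") else list(X)
        rows = [
            [psg_features(g, self.zero_tol, self.include_zeros)[name] for name in FEATURE_NAMES]
            for g in graphs
        ]
        return np.asarray(rows, dtype=float)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
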