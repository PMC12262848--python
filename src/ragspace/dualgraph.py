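"""Dual-graph data model for coarse-grained RNA topologies.

A dual graph represents an RNA secondary/tertiary fold with one vertex per
double-helical stem and one edge per single-stranded segment connecting
stems (bulges, loops, junction strands).  Self-loops (hairpins) are recorded
as a diagonal entry of 2; up to three parallel edges may join a vertex pair
(pseudoknots).  Because a helix exposes four strand ends and the chain's
3'/5' termini carry no edge, a valid topology on ``n`` vertices satisfies:

* symmetric non-negative integer adjacency matrix,
* diagonal entries in {0, 2}, off-diagonal entries in {0, 1, 2, 3},
* every vertex degree (off-diagonal row sum + diagonal) at most 4,
* total matrix entry sum exactly ``4n - 2``,
* connectivity.

Topology *identity* within a catalog is isomorphism of the loopless skeleton
multigraph: the number of self-loops is fixed by the degree-sum rule and
their placement is a representative choice that does not distinguish
catalogued topologies (this is the identity that reproduces the published
per-vertex catalog sizes).  ``canonical_key`` distinguishes full multigraphs
including loop placement; ``skeleton_key`` is the catalog identity.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import igraph as ig
import numpy as np

__all__ = [
    "DualGraph",
    "GraphID",
    "is_valid_dual_graph",
    "validity_errors",
    "laplacian",
    "fiedler_number",
    "canonical_key",
    "skeleton_key",
    "parse_graph_id",
    "format_graph_id",
]

_ID_RE = re.compile(r"^(\d+)_(\d+)$")


class InputError(ValueError):
    """Raised for malformed inputs (non-square matrices, bad IDs, ...)."""


def _as_int_matrix(A) -> np.ndarray:
    M = np.asarray(A)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise InputError(f"adjacency matrix must be square, got shape {M.shape}")
    if M.size == 0:
        raise InputError("adjacency matrix must be non-empty")
    if not np.issubdtype(M.dtype, np.integer):
        if np.issubdtype(M.dtype, np.floating) and np.all(M == np.round(M)):
            M = M.astype(np.int64)
        else:
            raise InputError("adjacency matrix must have integer entries")
    return M.astype(np.int64)


def _connected(A: np.ndarray) -> bool:
    n = A.shape[0]
    seen = {0}
    stack = [0]
    off = A.copy()
    np.fill_diagonal(off, 0)
    while stack:
        v = stack.pop()
        for u in np.nonzero(off[v])[0]:
            if u not in seen:
                seen.add(int(u))
                stack.append(int(u))
    return len(seen) == n


def validity_errors(A) -> list[str]:
    """All dual-graph rule violations of ``A`` (empty list == valid)."""
    M = _as_int_matrix(A)
    n = M.shape[0]
    problems = []
    if n < 2:
        problems.append("a dual graph needs at least 2 vertices")
    if not np.array_equal(M, M.T):
        problems.append("adjacency matrix is not symmetric")
    d = np.diag(M)
    if not np.all((d == 0) | (d == 2)):
        problems.append("diagonal entries must be 0 (no hairpin) or 2 (hairpin)")
    off = M.copy()
    np.fill_diagonal(off, 0)
    if off.min() < 0 or off.max() > 3:
        problems.append("off-diagonal entries must lie in {0,1,2,3}")
    if problems:
        return problems
    deg = off.sum(axis=1) + d
    if deg.max() > 4:
        problems.append(f"vertex degree exceeds 4 (max {int(deg.max())})")
    total = int(M.sum())
    if total != 4 * n - 2:
        problems.append(f"total entry sum {total} != 4n-2 = {4 * n - 2}")
    if not _connected(M):
        problems.append("graph is not connected")
    return problems


def is_valid_dual_graph(A) -> bool:
    """True iff ``A`` satisfies every dual-graph invariant.

    Raises :class:`InputError` for non-square or non-integer input.
    """
    return not validity_errors(A)


class DualGraph:
    """Immutable dual graph backed by its adjacency matrix."""

    __slots__ = ("A",)

    def __init__(self, A, validate: bool = True):
        M = _as_int_matrix(A)
        if validate:
            problems = validity_errors(M)
            if problems:
                raise InputError("invalid dual graph: " + "; ".join(problems))
        M.setflags(write=False)
        object.__setattr__(self, "A", M)

    def __setattr__(self, *a):  # pragma: no cover - immutability guard
        raise AttributeError("DualGraph is immutable")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def m(self) -> int:
        """Edge count: multi-edges counted with multiplicity, loops once."""
        off = self.offdiag()
        return int(off.sum() // 2 + np.trace(self.A) // 2)

    def offdiag(self) -> np.ndarray:
        off = self.A.copy()
        np.fill_diagonal(off, 0)
        return off

    def degrees(self) -> np.ndarray:
        return self.offdiag().sum(axis=1) + np.diag(self.A)

    @property
    def loop_count(self) -> int:
        return int(np.trace(self.A) // 2)

    def skeleton_edges(self) -> list[tuple[int, int, int]]:
        """Loopless (i, j, multiplicity) triples, i < j."""
        off = self.offdiag()
        return [
            (i, j, int(off[i, j]))
            for i in range(self.n)
            for j in range(i + 1, self.n)
            if off[i, j]
        ]

    def permuted(self, perm: Sequence[int]) -> "DualGraph":
        """Relabel vertices: vertex ``v`` moves to position ``perm[v]``."""
        p = np.asarray(perm)
        inv = np.empty_like(p)
        inv[p] = np.arange(len(p))
        return DualGraph(self.A[np.ix_(inv, inv)], validate=False)

    def __eq__(self, other):
        return isinstance(other, DualGraph) and np.array_equal(self.A, other.A)

    def __hash__(self):
        return hash(self.A.tobytes())

    def __repr__(self):
        return f"DualGraph(n={self.n}, m={self.m})"


# ---------------------------------------------------------------------------
# canonical forms
# ---------------------------------------------------------------------------

def _colored_encoding(g: DualGraph, with_loops: bool):
    """Simple vertex-colored graph encoding of the multigraph.

    Multiplicity-w edges (w>=2) become a subdivision vertex of color w+1;
    self-loops become vertex color 1.  BLISS canonicalization of this
    encoding induces a canonical form of the (multi)graph.
    """
    n = g.n
    if with_loops:
        colors = [int(g.A[i, i] // 2) for i in range(n)]
    else:
        colors = [0] * n
    edges = []
    nv = n
    for i, j, w in g.skeleton_edges():
        if w == 1:
            edges.append((i, j))
        else:
            colors.append(w + 1)
            edges.append((i, nv))
            edges.append((j, nv))
            nv += 1
    return nv, colors, edges


def _canon(nv: int, colors: list[int], edges: list[tuple[int, int]]):
    graph = ig.Graph(nv, edges)
    perm = graph.canonical_permutation(color=colors)
    relabeled = graph.permute_vertices(perm)
    ccolors = [0] * nv
    for v, c in enumerate(colors):
        ccolors[perm[v]] = c
    ces = sorted(tuple(sorted(e)) for e in relabeled.get_edgelist())
    return perm, ccolors, ces


def canonical_key(g: DualGraph) -> str:
    """Canonical key of the vertex-labeled multigraph *including* loops.

    Two dual graphs have equal keys iff they are isomorphic as multigraphs
    with self-loops.
    """
    nv, colors, edges = _colored_encoding(g, with_loops=True)
    _, ccolors, ces = _canon(nv, colors, edges)
    return f"{g.n}|{','.join(map(str, ccolors))}|{';'.join(f'{a}-{b}' for a, b in ces)}"


def skeleton_key(g: DualGraph) -> str:
    """Canonical key of the loopless skeleton multigraph (catalog identity)."""
    nv, colors, edges = _colored_encoding(g, with_loops=False)
    _, ccolors, ces = _canon(nv, colors, edges)
    return f"{g.n}|{','.join(map(str, ccolors))}|{';'.join(f'{a}-{b}' for a, b in ces)}"


def skeleton_canonical_permutation(g: DualGraph) -> list[int]:
    """Canonical relabeling of the original vertices under skeleton identity."""
    nv, colors, edges = _colored_encoding(g, with_loops=False)
    perm, _, _ = _canon(nv, colors, edges)
    # BLISS permutes subdivision helper vertices too; keep only the original
    # vertices and rank them by their canonical position.
    orig = perm[: g.n]
    order = np.argsort(orig)  # original vertices ranked by canonical position
    rank = np.empty(g.n, dtype=int)
    rank[order] = np.arange(g.n)
    return rank.tolist()


# ---------------------------------------------------------------------------
# Laplacian / Fiedler
# ---------------------------------------------------------------------------

def laplacian(g: DualGraph) -> np.ndarray:
    """Multiplicity-weighted graph Laplacian ``L = D - A_off``.

    Self-loops cancel (they add to both the degree diagonal and the
    adjacency diagonal in the standard multigraph convention), so ``L``
    depends only on the loopless skeleton.  Rows sum to zero and ``L`` is
    positive semidefinite.
    """
    off = g.offdiag().astype(float)
    return np.diag(off.sum(axis=1)) - off


def laplacian_spectrum(g: DualGraph) -> np.ndarray:
    return np.linalg.eigvalsh(laplacian(g))


def fiedler_number(g: DualGraph) -> float:
    """Second-smallest Laplacian eigenvalue; > 0 iff connected."""
    ev = laplacian_spectrum(g)
    lam2 = float(ev[1])
    if lam2 <= 1e-9:
        raise ValueError("Fiedler number is only defined (positive) for connected graphs")
    return lam2


# ---------------------------------------------------------------------------
# graph IDs
# ---------------------------------------------------------------------------

class GraphID(str):
    """Catalog identifier ``"<vertices>_<rank>"`` (e.g. ``4_13``)."""

    @property
    def vertices(self) -> int:
        return parse_graph_id(self)[0]

    @property
    def rank(self) -> int:
        return parse_graph_id(self)[1]


def parse_graph_id(s: str) -> tuple[int, int]:
    m = _ID_RE.match(s.strip())
    if not m:
        raise InputError(f"malformed graph ID {s!r} (expected '<vertices>_<rank>')")
    a, k = int(m.group(1)), int(m.group(2))
    if a < 2 or k < 1:
        raise InputError(f"graph ID {s!r} out of range")
    return a, k


def format_graph_id(a: int, k: int) -> GraphID:
    return GraphID(f"{a}_{k}")
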