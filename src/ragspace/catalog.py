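"""Exhaustive enumeration of dual-graph topologies and catalog bookkeeping.

The enumerator generates every connected loopless skeleton multigraph with
multiplicity <= 3 and per-vertex degree <= 4 whose degree sum leaves an even,
placeable self-loop deficit (``4n - 2`` total strand ends minus the skeleton
degree sum, two per hairpin), rejecting skeleton isomorphs with BLISS
canonical forms.  Each class is stored once, as a canonically relabeled
representative with a deterministic hairpin placement.

Catalog IDs are ``a_k`` with ``a`` the vertex count and ``k`` the rank by
ascending Fiedler number (ties broken by the full Laplacian spectrum, then
the skeleton canonical key).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .dualgraph import (
    DualGraph,
    GraphID,
    InputError,
    fiedler_number,
    format_graph_id,
    laplacian_spectrum,
    parse_graph_id,
    skeleton_key,
    skeleton_canonical_permutation,
)

__all__ = ["GraphCatalog", "enumerate_dual_graphs", "assign_ids", "build_catalog"]

FIEDLER_TIE_TOL = 1e-9


@dataclass
class GraphCatalog:
    """Ordered mapping of :class:`GraphID` -> :class:`DualGraph` plus metadata."""

    graphs: dict[GraphID, DualGraph] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self) -> Iterator[GraphID]:
        return iter(self.graphs)

    def __getitem__(self, gid) -> DualGraph:
        return self.graphs[GraphID(gid)]

    def __contains__(self, gid) -> bool:
        return GraphID(gid) in self.graphs

    def items(self):
        return self.graphs.items()

    def ids(self) -> list[GraphID]:
        return list(self.graphs)

    def vertex_counts(self) -> list[int]:
        return sorted({parse_graph_id(g)[0] for g in self.graphs})

    def subset(self, vertices) -> "GraphCatalog":
        wanted = set(vertices)
        graphs = {
            gid: g for gid, g in self.graphs.items() if parse_graph_id(gid)[0] in wanted
        }
        return GraphCatalog(graphs, dict(self.metadata, subset=sorted(wanted)))

    def merged(self, other: "GraphCatalog") -> "GraphCatalog":
        graphs = dict(self.graphs)
        graphs.update(other.graphs)
        return GraphCatalog(graphs, dict(self.metadata))

    def skeleton_index(self) -> dict[str, GraphID]:
        """Map skeleton canonical key -> GraphID, for resolving subgraphs."""
        return {skeleton_key(g): gid for gid, g in self.graphs.items()}


# ---------------------------------------------------------------------------
# candidate generation
# ---------------------------------------------------------------------------

def _degree_sequences(n: int, total: int) -> list[tuple[int, ...]]:
    """Non-increasing sequences of n skeleton degrees in 1..4 summing to total."""
    out: list[tuple[int, ...]] = []

    def rec(rem, k, mx, cur):
        if k == 0:
            if rem == 0:
                out.append(tuple(cur))
            return
        hi = min(mx, rem - (k - 1))
        for d in range(hi, 0, -1):
            if d * k < rem:
                break
            cur.append(d)
            rec(rem - d, k - 1, d, cur)
            cur.pop()

    rec(total, n, 4, [])
    return out


def _offdiag_assignments(n: int, degs: tuple[int, ...]):
    """DFS over upper-triangular multiplicities (<=3) realizing ``degs``."""
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    resid = list(degs)
    entries: dict[tuple[int, int], int] = {}
    results: list[dict[tuple[int, int], int]] = []

    def rec(idx):
        if idx == len(pairs):
            results.append(dict(entries))
            return
        i, j = pairs[idx]
        if resid[i] > 3 * (n - j):  # vertex i can no longer be saturated
            return
        hi = min(3, resid[i], resid[j])
        last = j == n - 1
        for w in range(hi, -1, -1):
            if last and resid[i] != w:
                continue
            resid[i] -= w
            resid[j] -= w
            if w:
                entries[(i, j)] = w
            rec(idx + 1)
            if w:
                del entries[(i, j)]
            resid[i] += w
            resid[j] += w

    rec(0)
    return results


def _skeleton_connected(n: int, edges) -> bool:
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    root = find(0)
    return all(find(v) == root for v in range(n))


def complete_with_loops(skeleton: np.ndarray) -> np.ndarray:
    """Add the hairpin loops required by the degree-sum rule.

    The loop count is fixed at ``(4n - 2 - degree sum) / 2``; loops are placed
    deterministically on the lowest-degree eligible vertices (skeleton degree
    <= 2, lowest index first).  Raises :class:`InputError` if no placement
    exists.
    """
    A = np.array(skeleton, dtype=np.int64)
    np.fill_diagonal(A, 0)
    n = A.shape[0]
    sdeg = A.sum(axis=1)
    deficit = 4 * n - 2 - int(sdeg.sum())
    if deficit < 0 or deficit % 2:
        raise InputError("skeleton degree sum incompatible with a dual graph")
    nloops = deficit // 2
    eligible = sorted(range(n), key=lambda v: (sdeg[v], v))
    eligible = [v for v in eligible if sdeg[v] <= 2]
    if nloops > len(eligible):
        raise InputError("not enough low-degree vertices to place hairpin loops")
    for v in eligible[:nloops]:
        A[v, v] = 2
    return A


def enumerate_dual_graphs(n: int, progress: bool = False) -> GraphCatalog:
    """All non-isomorphic dual-graph topologies on ``n`` vertices, with IDs.

    Topology identity is skeleton isomorphism (see :mod:`ragspace.dualgraph`).
    """
    if n < 2:
        raise InputError("dual graphs need at least 2 vertices")
    t0 = time.time()
    reps: dict[str, DualGraph] = {}
    max_loops = n  # loop needs skeleton degree <= 2, so this is generous
    for nloops in range(0, max_loops + 1):
        total = 4 * n - 2 - 2 * nloops
        if total < 2 * (n - 1):
            break  # too few skeleton edge ends to stay connected
        for degs in _degree_sequences(n, total):
            if sum(1 for d in degs if d <= 2) < nloops:
                continue
            for entries in _offdiag_assignments(n, degs):
                if not _skeleton_connected(n, entries):
                    continue
                A = np.zeros((n, n), dtype=np.int64)
                for (i, j), w in entries.items():
                    A[i, j] = A[j, i] = w
                g = DualGraph(complete_with_loops(A))
                key = skeleton_key(g)
                if key not in reps:
                    # store a canonical representative so the catalog does not
                    # depend on generation order
                    perm = skeleton_canonical_permutation(g)
                    gc = DualGraph(
                        complete_with_loops(g.permuted(perm).offdiag()), validate=True
                    )
                    reps[key] = gc
    catalog = GraphCatalog(
        {GraphID(f"tmp_{i}"): g for i, g in enumerate(reps.values())},
        {
            "vertex_range": [n, n],
            "generator": "ragspace.enumerate_dual_graphs",
            "elapsed_s": round(time.time() - t0, 2),
        },
    )
    if progress:  # pragma: no cover - cosmetic
        print(f"n={n}: {len(catalog)} topologies in {catalog.metadata['elapsed_s']}s")
    return assign_ids(catalog, n=n)


def assign_ids(catalog: GraphCatalog, n: int | None = None, descending: bool = False) -> GraphCatalog:
    """Rank a single-vertex-count catalog by Fiedler number and assign ``a_k`` IDs.

    ``k = 1`` is the smallest Fiedler number (``descending=True`` reverses the
    rank order).  Ties within ``1e-9`` are broken by the full sorted Laplacian
    spectrum, then by the skeleton canonical key.
    """
    graphs = list(catalog.graphs.values())
    if not graphs:
        return GraphCatalog({}, dict(catalog.metadata))
    counts = {g.n for g in graphs}
    if len(counts) > 1:
        raise InputError(f"assign_ids needs a single vertex count, got {sorted(counts)}")
    nv = counts.pop()
    if n is not None and n != nv:
        raise InputError(f"catalog holds {nv}-vertex graphs, expected {n}")

    def sort_key(g: DualGraph):
        spec = laplacian_spectrum(g)
        fiedler = round(float(spec[1]) / FIEDLER_TIE_TOL) * FIEDLER_TIE_TOL
        return (fiedler, tuple(np.round(spec, 9)), skeleton_key(g))

    graphs.sort(key=sort_key, reverse=descending)
    out = {format_graph_id(nv, k + 1): g for k, g in enumerate(graphs)}
    meta = dict(catalog.metadata, id_order="descending" if descending else "ascending")
    return GraphCatalog(out, meta)


def build_catalog(n_min: int = 2, n_max: int = 7, progress: bool = False) -> GraphCatalog:
    """Enumerate and merge catalogs for a vertex range."""
    if n_min < 2 or n_max < n_min:
        raise InputError("need 2 <= n_min <= n_max")
    merged = GraphCatalog({}, {"vertex_range": [n_min, n_max]})
    for n in range(n_min, n_max + 1):
        merged = merged.merged(enumerate_dual_graphs(n, progress=progress))
    merged.metadata["vertex_range"] = [n_min, n_max]
    return merged
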