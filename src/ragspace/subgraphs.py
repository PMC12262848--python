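"""Separability of dual graphs into smaller valid dual graphs.

An RNA motif is *separable* when it can be partitioned into smaller motifs
that are themselves valid dual graphs; junctions and pseudoknots are
preserved because no edge is ever severed.  The split model shares one stem
between the two parts: a split vertex ``v`` is duplicated, each part keeps
the component(s) of ``G - v`` on its side plus all of v's edges into that
side, and the chain cut at the shared helix is capped with a hairpin.  The
degree-sum law fixes the cap bookkeeping exactly: the two copies of ``v``
carry ``2*loop(v) + 2`` diagonal units between them (one new hairpin when
``v`` had none, hairpins on both copies when it did).  Part sizes therefore
satisfy ``n1 + n2 = n + 1``.

A split is kept only when *both* parts are valid dual graphs (degree cap,
degree sum, connectivity); recursion collects sub-dual-graphs at all scales,
deduplicated by skeleton canonical form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import GraphCatalog
from .dualgraph import DualGraph, GraphID, is_valid_dual_graph, skeleton_key

__all__ = ["DecompositionResult", "decompose", "separability_profile"]


@dataclass
class DecompositionResult:
    source: GraphID | None
    separable: bool
    subgraphs: list[tuple[DualGraph, GraphID | None]] = field(default_factory=list)

    def subgraph_ids(self) -> list[GraphID | None]:
        return [gid for _, gid in self.subgraphs]


def _components_without(off: np.ndarray, v: int) -> list[list[int]]:
    n = off.shape[0]
    comp: dict[int, int] = {}
    cid = 0
    for s in range(n):
        if s == v or s in comp:
            continue
        stack = [s]
        comp[s] = cid
        while stack:
            x = stack.pop()
            for u in np.nonzero(off[x])[0]:
                u = int(u)
                if u != v and u not in comp:
                    comp[u] = cid
                    stack.append(u)
        cid += 1
    groups: dict[int, list[int]] = {}
    for u, c in comp.items():
        groups.setdefault(c, []).append(u)
    return list(groups.values())


def _split_parts(A: np.ndarray, v: int, side1: list[int], side2: list[int]):
    """Both parts of the vertex-sharing split, or None if invalid.

    The split vertex's self-loop budget on the two copies is fixed by the
    degree-sum law: lv1 + lv2 = 2*loop(v) + 2.
    """
    loop_v = int(A[v, v])
    parts = []
    for side in (side1, side2):
        p = sorted(side + [v])
        sub = A[np.ix_(p, p)].copy()
        iv = p.index(v)
        sub[iv, iv] = 0
        k = len(p)
        lv = 4 * k - 2 - int(sub.sum())
        if lv not in (0, 2):
            return None
        sub[iv, iv] = lv
        parts.append((sub, lv))
    if parts[0][1] + parts[1][1] != 2 * loop_v + 2:
        return None
    out = []
    for sub, _ in parts:
        if not is_valid_dual_graph(sub):
            return None
        out.append(DualGraph(sub))
    return out


def _all_splits(g: DualGraph):
    """Every valid single vertex-sharing split of ``g``."""
    A = np.asarray(g.A)
    off = g.offdiag()
    for v in range(g.n):
        comps = _components_without(off, v)
        if len(comps) < 2:
            continue
        k = len(comps)
        for mask in range(1, 2 ** (k - 1)):
            side1 = [u for b in range(k) if (mask >> b) & 1 for u in comps[b]]
            side2 = [u for b in range(k) if not (mask >> b) & 1 for u in comps[b]]
            parts = _split_parts(A, v, side1, side2)
            if parts is not None:
                yield parts


def decompose(g: DualGraph, catalog: GraphCatalog | None = None) -> DecompositionResult:
    """All sub-dual-graphs of ``g`` under the vertex-sharing split model.

    Subgraphs are collected recursively at every scale and deduplicated by
    skeleton canonical form; when ``catalog`` is given each part is resolved
    to its :class:`GraphID` (None when outside the catalog's vertex range).
    ``separable`` is True iff at least one valid split exists.
    """
    index = catalog.skeleton_index() if catalog is not None else {}
    source = index.get(skeleton_key(g))
    seen: dict[str, DualGraph] = {}

    def walk(h: DualGraph):
        for parts in _all_splits(h):
            for part in parts:
                key = skeleton_key(part)
                if key not in seen:
                    seen[key] = part
                    walk(part)

    walk(g)
    subs = [(part, index.get(key)) for key, part in sorted(seen.items())]
    return DecompositionResult(source, bool(subs), subs)


def separability_profile(graphs, catalog: GraphCatalog | None = None):
    """Per-graph separable flags plus the aggregate separable fraction."""
    graphs = list(graphs)
    flags = [decompose(g, catalog).separable for g in graphs]
    fraction = sum(flags) / len(flags) if flags else 0.0
    return {"separable": flags, "fraction": fraction}
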