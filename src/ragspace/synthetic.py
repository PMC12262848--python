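"""Synthetic stand-ins for the known-RNA label lists and for clustering fixtures.

Real label lists (graph IDs of topologies matched to solved 3D structures)
come from structure-census releases; the synthetic generator emulates their
two salient properties: per-vertex-count totals matching the published
census sizes, and a strong bias toward topologies that look biological —
separable into sub-dual-graphs and free of persistent 1-cycles — which is
the signature reported for real RNA motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import GraphCatalog
from .cluster import LabelSet
from .dualgraph import InputError, parse_graph_id
from .persistence import separ_pattern_report
from .subgraphs import decompose

__all__ = [
    "DEFAULT_COUNTS_2021",
    "DEFAULT_COUNTS_2022",
    "SyntheticLabelSpec",
    "generate_synthetic_labels",
    "make_two_cluster_features",
]

# Known-RNA census sizes per vertex count (4..9) for the two vintages the
# catalogs are usually trained/validated against.
DEFAULT_COUNTS_2021: dict[int, int] = {4: 17, 5: 20, 6: 22, 7: 21, 8: 14, 9: 17}
DEFAULT_COUNTS_2022: dict[int, int] = {4: 22, 5: 29, 6: 37, 7: 34, 8: 20, 9: 28}


@dataclass(frozen=True)
class SyntheticLabelSpec:
    """Recipe for a synthetic known-RNA label set.

    ``counts`` maps vertex count -> number of labels; ``bias`` is the extra
    sampling weight given to biological-looking graphs: a graph's weight is
    ``1 + bias*separable + bias*no_betti1_bar`` (``bias=0`` is uniform).
    """

    counts: dict = field(default_factory=lambda: dict(DEFAULT_COUNTS_2021))
    bias: float = 9.0
    seed: int = 0


def _bio_scores(catalog: GraphCatalog, ids) -> np.ndarray:
    graphs = [catalog[g] for g in ids]
    flags = separ_pattern_report(graphs)
    seps = [decompose(g).separable for g in graphs]
    return np.array(
        [int(s) + int(not f["has_betti1_bar"]) for s, f in zip(seps, flags)],
        dtype=float,
    )


def generate_synthetic_labels(
    spec: SyntheticLabelSpec,
    catalog: GraphCatalog,
    exclude: LabelSet | None = None,
    provenance: str = "synthetic",
) -> LabelSet:
    """Seeded sample of catalog IDs honoring the recipe's counts and bias.

    ``exclude`` supports later-vintage extensions: pass the earlier label set
    to draw a disjoint sample (as newly solved structures would be).
    """
    rng = np.random.default_rng(spec.seed)
    chosen: list[str] = []
    for v, count in sorted(spec.counts.items()):
        ids = [g for g in catalog.ids() if parse_graph_id(g)[0] == v]
        if exclude is not None:
            ids = [g for g in ids if g not in exclude]
        if count > len(ids):
            raise InputError(
                f"requested {count} labels for {v}-vertex graphs but only "
                f"{len(ids)} are available"
            )
        if not ids:
            continue
        weights = 1.0 + spec.bias * _bio_scores(catalog, ids)
        p = weights / weights.sum()
        take = rng.choice(len(ids), size=count, replace=False, p=p)
        chosen.extend(ids[i] for i in take)
    return LabelSet(frozenset(chosen), provenance=f"{provenance}:seed={spec.seed}")


def make_two_cluster_features(
    n_samples: int = 1000,
    separation: float = 6.0,
    n_features: int = 19,
    labeled_frac: float = 0.01,
    seed: int = 0,
) -> tuple[pd.DataFrame, LabelSet, np.ndarray]:
    """Two spherical Gaussian blobs with centers ``separation`` sigmas apart.

    Returns a feature table with synthetic graph IDs, a label set sampling
    ``labeled_frac`` of the first blob (the planted RNA-like cluster), and
    the planted blob membership.  Used to verify that every clustering
    backend recovers a well-separated planted partition.  The labeled
    census is deliberately sparse — in the real catalogs known RNAs are a
    fraction of a percent of all topologies.
    """
    rng = np.random.default_rng(seed)
    n1 = n_samples // 2
    n2 = n_samples - n1
    direction = rng.normal(size=n_features)
    direction /= np.linalg.norm(direction)
    offset = separation * direction
    X = np.vstack(
        [rng.normal(size=(n1, n_features)), rng.normal(size=(n2, n_features)) + offset]
    )
    membership = np.array([1] * n1 + [0] * n2)
    perm = rng.permutation(n_samples)
    X, membership = X[perm], membership[perm]
    ids = [f"9_{i + 1}" for i in range(n_samples)]
    df = pd.DataFrame(X, index=ids, columns=[f"f{i}" for i in range(n_features)])
    blob1 = [i for i, m in zip(ids, membership) if m == 1]
    k = max(1, int(labeled_frac * len(blob1)))
    labeled = rng.choice(len(blob1), size=k, replace=False)
    labels = LabelSet(frozenset(blob1[i] for i in labeled), provenance=f"planted:seed={seed}")
    return df, labels, membership
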