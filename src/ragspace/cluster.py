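"""Two-cluster RNA-likeness analysis of PSG feature tables.

All possible topologies are partitioned into exactly two clusters by one of
six algorithms; the cluster holding the majority of the known-RNA labels is
designated *RNA-like*.  Distance to the RNA-like centroid (in standardized
feature space) ranks hypothetical topologies by their likelihood of being
realizable RNA motifs.  Sensitivity — the percentage of known-RNA graphs
landing in the RNA-like cluster — is the primary performance metric, with
silhouette and homogeneity as secondary checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import (
    AgglomerativeClustering,
    Birch,
    KMeans,
    MiniBatchKMeans,
    SpectralClustering,
)
from sklearn.decomposition import PCA
from sklearn.metrics import homogeneity_score, silhouette_score
from sklearn.mixture import GaussianMixture
from sklearn.preprocessing import StandardScaler

from .dualgraph import GraphID, InputError, parse_graph_id

__all__ = [
    "METHODS",
    "CapabilityError",
    "LabelSet",
    "ClusterResult",
    "MetricsReport",
    "RNALikeClusterer",
    "make_datasets",
    "standardize",
    "run_clustering",
    "designate_rna_like",
    "evaluate",
    "rank_by_center",
    "consensus_top",
    "pca_embed",
    "validate_against",
]

METHODS = ("kmeans", "minibatch_kmeans", "gmm", "ward", "spectral", "birch")

DATASET_SPLITS: dict[str, tuple[int, ...]] = {
    "V4&5": (4, 5),
    "V6": (6,),
    "V7": (7,),
    "V8": (8,),
    "V9": (9,),
}


class CapabilityError(RuntimeError):
    """A method cannot run on this input (e.g. Ward above its size guard)."""


@dataclass(frozen=True)
class LabelSet:
    """GraphIDs of topologies matched to experimentally known RNA structures."""

    ids: frozenset
    provenance: str = ""

    def __post_init__(self):
        if not self.ids:
            raise InputError("a label set must be non-empty")
        object.__setattr__(self, "ids", frozenset(GraphID(i) for i in self.ids))

    def __contains__(self, gid) -> bool:
        return GraphID(gid) in self.ids

    def __len__(self) -> int:
        return len(self.ids)

    def indicator(self, index) -> np.ndarray:
        return np.asarray([1 if GraphID(i) in self.ids else 0 for i in index])


@dataclass
class ClusterResult:
    method: str
    assignment: pd.Series          # 1 = RNA-like, 0 = non-RNA-like, per GraphID
    raw_assignment: pd.Series      # untranslated backend cluster labels
    centers: np.ndarray            # row 0: non-RNA-like, row 1: RNA-like centroid
    distance_own: pd.Series        # distance to the graph's own cluster center
    distance_rna: pd.Series        # distance to the RNA-like center
    labels: LabelSet | None
    seed: int | None
    standardized: pd.DataFrame = field(repr=False, default=None)
    designation_tie: bool = False


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float             # % of labeled graphs inside the RNA-like cluster
    silhouette: float
    homogeneity: float
    rna_like_share: float          # % of all graphs designated RNA-like
    rna_like_share_hypothetical: float  # same, restricted to unlabeled graphs

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "silhouette": self.silhouette,
            "homogeneity": self.homogeneity,
            "rna_like_share": self.rna_like_share,
            "rna_like_share_hypothetical": self.rna_like_share_hypothetical,
        }


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class RNALikeClusterer(ClusterMixin, BaseEstimator):
    """Two-cluster partition with RNA-like designation from known-RNA labels.

    Parameters
    ----------
    method : one of ``kmeans``, ``minibatch_kmeans``, ``gmm``, ``ward``,
        ``spectral``, ``birch``.
    standardize : z-score features before clustering (the eigenvalue-sum
        features dwarf the count features otherwise).
    random_state : seed for the stochastic backends.
    ward_max_rows : Ward's O(n^3) agglomeration is refused above this size.
    spectral_nn_above : switch spectral clustering to a nearest-neighbours
        affinity above this row count (dense RBF affinity is quadratic).
    designation : ``majority`` designates the cluster with the larger labeled
        *count* as RNA-like; ``percentage`` uses the larger labeled share.

    Attributes (after ``fit(X, y)`` with ``y`` the known-RNA indicator)
    ----------
    labels_ : ndarray of 0/1, 1 = RNA-like cluster.
    raw_labels_ : backend cluster labels before designation.
    rna_like_cluster_ : backend label designated RNA-like.
    cluster_centers_ : (2, p) centroids in the clustering feature space,
        row 1 = RNA-like.
    distances_ : (n,) Euclidean distance of each sample to the RNA-like center.
    designation_tie_ : True when the labeled counts tied (smaller cluster wins).
    """

    def __init__(
        self,
        method: str = "kmeans",
        *,
        standardize: bool = True,
        random_state: int = 0,
        n_init: int = 10,
        batch_size: int = 1024,
        ward_max_rows: int = 30_000,
        spectral_nn_above: int = 3000,
        designation: str = "majority",
    ):
        self.method = method
        self.standardize = standardize
        self.random_state = random_state
        self.n_init = n_init
        self.batch_size = batch_size
        self.ward_max_rows = ward_max_rows
        self.spectral_nn_above = spectral_nn_above
        self.designation = designation

    # -- backends ----------------------------------------------------------
    def _backend(self, n_rows: int):
        rs = self.random_state
        if self.method == "kmeans":
            return KMeans(n_clusters=2, n_init=self.n_init, random_state=rs)
        if self.method == "minibatch_kmeans":
            return MiniBatchKMeans(
                n_clusters=2, batch_size=self.batch_size, n_init=self.n_init,
                random_state=rs,
            )
        if self.method == "gmm":
            return GaussianMixture(
                n_components=2, covariance_type="full", random_state=rs
            )
        if self.method == "ward":
            if n_rows > self.ward_max_rows:
                raise CapabilityError(
                    f"ward clustering refused for {n_rows} rows "
                    f"(O(n^3); guard at {self.ward_max_rows})"
                )
            return AgglomerativeClustering(n_clusters=2, linkage="ward")
        if self.method == "spectral":
            affinity = "nearest_neighbors" if n_rows > self.spectral_nn_above else "rbf"
            return SpectralClustering(
                n_clusters=2, affinity=affinity, random_state=rs,
                assign_labels="kmeans",
            )
        if self.method == "birch":
            return Birch(n_clusters=2)
        raise InputError(f"unknown clustering method {self.method!r}; pick from {METHODS}")

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise InputError("X must be 2-dimensional")
        if y is None:
            raise InputError("fit requires y: a 0/1 known-RNA indicator per row")
        y = np.asarray(y).astype(int)
        if y.shape[0] != X.shape[0]:
            raise InputError("y length must match X rows")
        if y.sum() == 0:
            raise InputError("designation needs at least one known-RNA (y == 1) row")
        self.n_features_in_ = X.shape[1]
        if self.standardize:
            self.scaler_ = StandardScaler().fit(X)
            Z = self.scaler_.transform(X)
        else:
            self.scaler_ = None
            Z = X
        backend = self._backend(Z.shape[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = np.asarray(backend.fit_predict(Z)).astype(int)
        self.raw_labels_ = raw
        self.rna_like_cluster_, self.designation_tie_ = _designate(
            raw, y, self.designation
        )
        self.labels_ = (raw == self.rna_like_cluster_).astype(int)
        centers = np.vstack(
            [
                Z[raw != self.rna_like_cluster_].mean(axis=0)
                if np.any(raw != self.rna_like_cluster_)
                else np.full(Z.shape[1], np.nan),
                Z[raw == self.rna_like_cluster_].mean(axis=0),
            ]
        )
        self.cluster_centers_ = centers
        self.distances_ = np.linalg.norm(Z - centers[1], axis=1)
        self._Z = Z
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_

    def predict(self, X):
        """Nearest-centroid RNA-likeness (1 = RNA-like) for new samples."""
        Z = np.asarray(X, dtype=float)
        if self.scaler_ is not None:
            Z = self.scaler_.transform(Z)
        d = np.linalg.norm(Z[:, None, :] - self.cluster_centers_[None], axis=2)
        return np.argmin(d, axis=1)


def _designate(raw: np.ndarray, y: np.ndarray, mode: str) -> tuple[int, bool]:
    counts = {c: int(((raw == c) & (y == 1)).sum()) for c in (0, 1)}
    if mode == "percentage":
        sizes = {c: max(int((raw == c).sum()), 1) for c in (0, 1)}
        score = {c: counts[c] / sizes[c] for c in (0, 1)}
    elif mode == "majority":
        score = dict(counts)
    else:
        raise InputError(f"unknown designation mode {mode!r}")
    if score[0] == score[1]:
        # tie: designate the smaller cluster (flagged)
        sizes = {c: int((raw == c).sum()) for c in (0, 1)}
        winner = min(sizes, key=lambda c: (sizes[c], c))
        warnings.warn("RNA-like designation tie; choosing the smaller cluster")
        return winner, True
    return max(score, key=lambda c: (score[c], c)), False


# ---------------------------------------------------------------------------
# functional layer over the estimator
# ---------------------------------------------------------------------------

def make_datasets(features: pd.DataFrame, names=None) -> dict[str, pd.DataFrame]:
    """Named vertex-grouped splits of a feature table (2- and 3-vertex rows
    are never included: they are all known RNAs and carry no signal).

    ``names=None`` builds every split fully covered by the available vertex
    range plus ``All`` (union of all vertices >= 4 present).  Requesting a
    split explicitly raises when its vertex range is missing.
    """
    vertices = pd.Series(
        [parse_graph_id(i)[0] for i in features.index], index=features.index
    )
    available = set(vertices.unique())
    out: dict[str, pd.DataFrame] = {}
    requested = names
    if requested is None:
        requested = [k for k, vs in DATASET_SPLITS.items() if set(vs) <= available]
        requested.append("All")
    for name in requested:
        if name == "All":
            mask = vertices >= 4
            if not mask.any():
                raise InputError("dataset 'All' needs vertices >= 4")
        else:
            if name not in DATASET_SPLITS:
                raise InputError(f"unknown dataset name {name!r}")
            vs = DATASET_SPLITS[name]
            missing = set(vs) - available
            if missing:
                raise InputError(f"dataset {name!r} needs vertices {sorted(missing)}")
            mask = vertices.isin(vs)
        out[name] = features.loc[mask]
    return out


def standardize(features: pd.DataFrame) -> tuple[pd.DataFrame, StandardScaler]:
    """Column-wise z-scores (constant columns map to 0) plus the transform."""
    if not all(np.issubdtype(dt, np.number) for dt in features.dtypes):
        raise InputError("feature table must be numeric")
    scaler = StandardScaler().fit(features.values)
    Z = pd.DataFrame(
        scaler.transform(features.values), index=features.index,
        columns=features.columns,
    )
    return Z, scaler


def run_clustering(
    features: pd.DataFrame, method: str, seed: int = 0, **kwargs
) -> pd.Series:
    """Raw 2-way assignment (cluster labels 0/1 with no RNA-like meaning)."""
    est = RNALikeClusterer(method, random_state=seed, standardize=False, **kwargs)
    backend = est._backend(len(features))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = np.asarray(backend.fit_predict(features.values)).astype(int)
    return pd.Series(raw, index=features.index, name="cluster")


def designate_rna_like(
    assignment: pd.Series,
    labels: LabelSet,
    features: pd.DataFrame,
    method: str = "",
    seed: int | None = None,
    designation: str = "majority",
) -> ClusterResult:
    """Translate a raw 2-way assignment into an RNA-like/non-RNA-like result.

    Centers are the per-cluster centroids of ``features`` (standardized
    feature space is expected); distances are Euclidean.
    """
    raw = assignment.astype(int)
    y = labels.indicator(assignment.index)
    if y.sum() == 0:
        raise InputError("no labeled graph present in the assignment")
    rna_cluster, tie = _designate(raw.values, y, designation)
    rna = (raw.values == rna_cluster).astype(int)
    Z = features.loc[assignment.index].values
    centers = np.vstack(
        [
            Z[rna == 0].mean(axis=0) if (rna == 0).any() else np.full(Z.shape[1], np.nan),
            Z[rna == 1].mean(axis=0),
        ]
    )
    d_rna = np.linalg.norm(Z - centers[1], axis=1)
    d_own = np.where(
        rna == 1, d_rna,
        np.linalg.norm(Z - centers[0], axis=1) if (rna == 0).any() else np.nan,
    )
    return ClusterResult(
        method=method,
        assignment=pd.Series(rna, index=assignment.index, name="rna_like"),
        raw_assignment=raw,
        centers=centers,
        distance_own=pd.Series(d_own, index=assignment.index),
        distance_rna=pd.Series(d_rna, index=assignment.index),
        labels=labels,
        seed=seed,
        standardized=features.loc[assignment.index],
        designation_tie=tie,
    )


def evaluate(result: ClusterResult, labels: LabelSet | None = None) -> MetricsReport:
    """Sensitivity, silhouette, homogeneity and RNA-like shares of a result."""
    labels = labels or result.labels
    y = labels.indicator(result.assignment.index)
    rna = result.assignment.values
    sens = 100.0 * float(rna[y == 1].sum()) / float(y.sum())
    Z = result.standardized.values
    if len(np.unique(rna)) == 2:
        sil = float(silhouette_score(Z, rna))
    else:
        sil = 0.0
    hom = float(homogeneity_score(y, rna))
    share = 100.0 * float(rna.mean())
    hyp = rna[y == 0]
    share_hyp = 100.0 * float(hyp.mean()) if hyp.size else float("nan")
    return MetricsReport(sens, sil, hom, share, share_hyp)


def rank_by_center(
    result: ClusterResult,
    labels: LabelSet | None = None,
    which: str = "rna_like",
    k: int = 15,
) -> list[GraphID]:
    """Top-k *hypothetical* members of a cluster by distance to its center.

    Ties are broken by GraphID so the ranking is deterministic.
    """
    labels = labels or result.labels
    if which not in ("rna_like", "non_rna_like"):
        raise InputError("which must be 'rna_like' or 'non_rna_like'")
    target = 1 if which == "rna_like" else 0
    y = labels.indicator(result.assignment.index)
    mask = (result.assignment.values == target) & (y == 0)
    Z = result.standardized.values[mask]
    center = result.centers[target]
    dist = np.linalg.norm(Z - center, axis=1)
    ids = result.assignment.index[mask]
    order = sorted(zip(dist, [parse_graph_id(i) for i in ids], ids))
    if k > len(order):
        warnings.warn(
            f"requested top {k} but only {len(order)} hypothetical graphs in the "
            f"{which} cluster"
        )
    return [GraphID(gid) for _, _, gid in order[:k]]


def consensus_top(rankings: dict[str, list], min_methods: int = 3) -> list[tuple[GraphID, int]]:
    """IDs appearing in >= min_methods of the supplied top-k lists, with counts."""
    counts: dict[GraphID, int] = {}
    for ids in rankings.values():
        for gid in set(map(GraphID, ids)):
            counts[gid] = counts.get(gid, 0) + 1
    picked = [(gid, c) for gid, c in counts.items() if c >= min_methods]
    picked.sort(key=lambda t: (-t[1], parse_graph_id(t[0])))
    return picked


def pca_embed(features: pd.DataFrame, n_components: int = 2):
    """First principal components for visualization (clustering itself runs
    in the full 19-dimensional space)."""
    if len(features) < n_components:
        raise InputError("need at least as many rows as components")
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(features.values)
    return (
        pd.DataFrame(
            coords, index=features.index,
            columns=[f"pc{i + 1}" for i in range(n_components)],
        ),
        pca,
    )


def validate_against(
    result: ClusterResult, later_labels: LabelSet, earlier_labels: LabelSet | None = None
) -> dict[int, int]:
    """Count later-vintage-only known RNAs inside the RNA-like cluster, by
    vertex count — the forward-validation a later structure census provides."""
    earlier = earlier_labels or result.labels
    new_ids = [
        gid for gid in result.assignment.index
        if gid in later_labels and (earlier is None or gid not in earlier)
    ]
    out: dict[int, int] = {}
    for gid in new_ids:
        if result.assignment[gid] == 1:
            v = parse_graph_id(gid)[0]
            out[v] = out.get(v, 0) + 1
    return out
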