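"""Two-cluster RNA-likeness machinery against from-formula oracles."""

import numpy as np
import pandas as pd
import pytest

from ragspace import (
    LabelSet,
    RNALikeClusterer,
    consensus_top,
    designate_rna_like,
    evaluate,
    make_datasets,
    make_two_cluster_features,
    pca_embed,
    rank_by_center,
    run_clustering,
    standardize,
    validate_against,
)
from ragspace.cluster import CapabilityError, METHODS
from ragspace.dualgraph import InputError


# ---------------------------------------------------------------------------
# independent metric oracles (plain formula implementations)
# ---------------------------------------------------------------------------

def silhouette_oracle(X, labels):
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n = len(X)
    D = np.linalg.norm(X[:, None] - X[None], axis=2)
    scores = []
    for i in range(n):
        own = labels == labels[i]
        a = D[i, own & (np.arange(n) != i)].mean()
        b = min(D[i, labels == c].mean() for c in np.unique(labels) if c != labels[i])
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def homogeneity_oracle(truth, pred):
    truth, pred = np.asarray(truth), np.asarray(pred)
    n = len(truth)

    def H(xs):
        _, counts = np.unique(xs, return_counts=True)
        p = counts / n
        return -(p * np.log(p)).sum()

    h_c = H(truth)
    if h_c == 0:
        return 1.0
    h_ck = 0.0
    for k in np.unique(pred):
        mask = pred == k
        pk = mask.sum() / n
        _, counts = np.unique(truth[mask], return_counts=True)
        pc = counts / mask.sum()
        h_ck += pk * -(pc * np.log(pc)).sum()
    return 1.0 - h_ck / h_c


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture()
def toy():
    """Six points, two obvious groups, two 'known RNA' points in group A."""
    X = pd.DataFrame(
        [[0.0, 0.1], [0.1, 0.0], [0.0, -0.1], [5.0, 5.1], [5.1, 5.0], [4.9, 5.0]],
        index=[f"4_{i + 1}" for i in range(6)],
        columns=["a", "b"],
    )
    raw = pd.Series([0, 0, 0, 1, 1, 1], index=X.index)
    labels = LabelSet(frozenset({"4_1", "4_2"}), "toy")
    return X, raw, labels


# ---------------------------------------------------------------------------
# dataset plumbing
# ---------------------------------------------------------------------------

def test_make_datasets_row_counts(features6):
    splits = make_datasets(features6)
    assert len(splits["V4&5"]) == 29 + 110
    assert len(splits["V6"]) == 508
    assert len(splits["All"]) == 29 + 110 + 508
    assert not splits["All"].index.duplicated().any()
    assert "V7" not in splits  # not covered by a 2..6 catalog
    with pytest.raises(InputError):
        make_datasets(features6, ["V7"])
    only6 = features6.loc[[i for i in features6.index if i.startswith("6_")]]
    assert len(make_datasets(only6, ["V6"])["V6"]) == 508
    with pytest.raises(InputError):
        make_datasets(only6, ["V4&5"])


def test_standardize_roundtrip(features6):
    Z, scaler = standardize(features6)
    live = features6.std(ddof=0) > 0
    assert np.allclose(Z.mean()[live], 0, atol=1e-12)
    assert np.allclose(Z.std(ddof=0)[live], 1)
    constant = pd.DataFrame({"c": [3.0, 3.0, 3.0]})
    assert (standardize(constant)[0]["c"] == 0).all()
    back = scaler.inverse_transform(Z.values)
    assert np.allclose(back, features6.values)


# ---------------------------------------------------------------------------
# clustering backends
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("method", METHODS)
def test_methods_recover_planted_blobs(method):
    """Each backend recovers a 6-sigma planted partition (up to the rare
    Gaussian tail points that genuinely cross the midplane)."""
    X, labels, membership = make_two_cluster_features(n_samples=240, seed=3)
    est = RNALikeClusterer(method, random_state=0)
    got = est.fit_predict(X.values, labels.indicator(X.index))
    assert (got == membership).mean() >= 0.97
    assert est.cluster_centers_.shape == (2, X.shape[1])
    assert est.distances_.shape == (len(X),)


def test_same_seed_same_assignment():
    X, labels, _ = make_two_cluster_features(n_samples=200, separation=2.0, seed=5)
    a = run_clustering(X, "kmeans", seed=7)
    b = run_clustering(X, "kmeans", seed=7)
    assert a.equals(b)


def test_ward_size_guard():
    X = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 3)))
    with pytest.raises(CapabilityError):
        RNALikeClusterer("ward", ward_max_rows=10).fit(
            X.values, np.r_[1, np.zeros(49, dtype=int)]
        )


def test_unknown_method_rejected():
    with pytest.raises(InputError):
        RNALikeClusterer("dbscan").fit(np.zeros((4, 2)), [1, 0, 0, 0])


# ---------------------------------------------------------------------------
# designation + metrics
# ---------------------------------------------------------------------------

def test_designation_majority(toy):
    X, raw, labels = toy
    res = designate_rna_like(raw, labels, X, method="toy")
    # labeled graphs 4_1, 4_2 sit in raw cluster 0 -> cluster 0 is RNA-like
    assert res.assignment.tolist() == [1, 1, 1, 0, 0, 0]
    flipped = designate_rna_like(1 - raw, labels, X, method="toy")
    assert flipped.assignment.tolist() == [1, 1, 1, 0, 0, 0]


def test_designation_tie_takes_smaller_cluster(toy):
    X, _, _ = toy
    raw = pd.Series([0, 0, 0, 0, 1, 1], index=X.index)
    labels = LabelSet(frozenset({"4_1", "4_5"}), "tie")
    with pytest.warns(UserWarning):
        res = designate_rna_like(raw, labels, X)
    assert res.designation_tie
    assert res.assignment.tolist() == [0, 0, 0, 0, 1, 1]


def test_designation_requires_labels(toy):
    X, raw, _ = toy
    outside = LabelSet(frozenset({"9_99"}), "absent")
    with pytest.raises(InputError):
        designate_rna_like(raw, outside, X)


def test_metrics_match_formula_oracles(toy):
    X, raw, labels = toy
    res = designate_rna_like(raw, labels, X)
    rep = evaluate(res)
    y = labels.indicator(X.index)
    assert rep.sensitivity == pytest.approx(100.0)
    assert rep.silhouette == pytest.approx(
        silhouette_oracle(X.values, res.assignment.values), abs=1e-9
    )
    assert rep.homogeneity == pytest.approx(
        homogeneity_oracle(y, res.assignment.values), abs=1e-9
    )
    assert rep.rna_like_share == pytest.approx(50.0)
    assert rep.rna_like_share_hypothetical == pytest.approx(25.0)


def test_sensitivity_complement(toy):
    """Sensitivity plus the labeled share in the non-RNA-like cluster is 100%."""
    X, raw, _ = toy
    labels = LabelSet(frozenset({"4_1", "4_4"}), "split")
    res = designate_rna_like(raw, labels, X)
    y = labels.indicator(X.index)
    rep = evaluate(res)
    other = 100.0 * ((res.assignment.values == 0) & (y == 1)).sum() / y.sum()
    assert rep.sensitivity + other == pytest.approx(100.0)


def test_metrics_relabeling_invariance(toy):
    X, raw, labels = toy
    a = evaluate(designate_rna_like(raw, labels, X))
    b = evaluate(designate_rna_like(1 - raw, labels, X))
    assert a == b


# ---------------------------------------------------------------------------
# ranking / consensus / embedding / validation
# ---------------------------------------------------------------------------

def test_rank_by_center_orders_by_distance(toy):
    X, raw, labels = toy
    res = designate_rna_like(raw, labels, X)
    # hypothetical member of the RNA-like cluster: only 4_3
    assert rank_by_center(res, which="rna_like", k=5) == ["4_3"]
    order = rank_by_center(res, which="non_rna_like", k=3)
    center = res.centers[0]
    dist = {i: np.linalg.norm(X.loc[i].values - center) for i in ("4_4", "4_5", "4_6")}
    assert order == sorted(dist, key=lambda i: (dist[i], int(i.split("_")[1])))
    with pytest.warns(UserWarning):
        rank_by_center(res, which="rna_like", k=10)


def test_point_at_centroid_ranks_first():
    X = pd.DataFrame(
        np.vstack([np.zeros(2), [[0.5, 0], [-0.5, 0], [0, 1], [9, 9], [9, 10]]]),
        index=[f"5_{i + 1}" for i in range(6)],
    )
    raw = pd.Series([0, 0, 0, 0, 1, 1], index=X.index)
    labels = LabelSet(frozenset({"5_2", "5_3", "5_4"}), "t")
    res = designate_rna_like(raw, labels, X)
    assert rank_by_center(res, k=1)[0] == "5_1"


def test_consensus_counting():
    same = {m: ["4_1", "4_2", "4_3"] for m in "abcde"}
    assert consensus_top(same, 3) == [("4_1", 5), ("4_2", 5), ("4_3", 5)]
    disjoint = {"a": ["4_1"], "b": ["4_2"], "c": ["4_3"]}
    assert consensus_top(disjoint, 3) == []
    overlap = {"a": ["4_1", "4_2"], "b": ["4_1", "4_3"], "c": ["4_1", "4_2"], "d": ["5_9"]}
    assert consensus_top(overlap, 2) == [("4_1", 3), ("4_2", 2)]


def test_pca_embedding_properties(rng):
    line = np.outer(rng.normal(size=40), [1.0, 2.0, -1.0])
    coords, pca = pca_embed(pd.DataFrame(line, index=[f"4_{i+1}" for i in range(40)]))
    assert pca.explained_variance_ratio_[0] == pytest.approx(1.0)
    assert np.allclose(coords["pc2"].std(), 0, atol=1e-9)
    with pytest.raises(InputError):
        pca_embed(pd.DataFrame(np.zeros((1, 3))))


def test_validate_against_counts(toy):
    X, raw, labels = toy
    res = designate_rna_like(raw, labels, X)
    # later vintage adds 4_3 (RNA-like side) and 4_6 (non-RNA-like side)
    later = LabelSet(labels.ids | {"4_3", "4_6"}, "later")
    assert validate_against(res, later) == {4: 1}
    # later vintage subset of earlier -> nothing new to confirm
    assert validate_against(res, LabelSet(frozenset({"4_1"}), "old")) == {}
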