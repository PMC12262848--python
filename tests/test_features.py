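"""Distance filtration, persistent Laplacians, and the 19-feature descriptor."""

import numpy as np
import pytest

from ragspace import (
    DualGraph,
    FEATURE_NAMES,
    PSGFeaturizer,
    build_filtration,
    featurize_catalog,
    persistent_laplacian,
    psg_features,
    spectrum,
)
from ragspace.dualgraph import InputError
from ragspace.features import boundary_matrix

from conftest import G_DOUBLE, G_SINGLE, G_TRIPLE

# hand-computed descriptors for the complete 2-vertex catalog:
# spectra per d are {0,0} (no edge yet) or {0,2} (one unweighted edge)
HAND = {
    G_SINGLE: {  # edge at d=1: spectra {0,2},{0,2},{0,2}; two hairpins
        "d1_sum": 2, "d1_nonzero_min": 2, "d1_variance": 1, "d1_zero_count": 1,
        "d2_sum": 2, "d2_nonzero_min": 2, "d2_max": 2, "d2_mean": 1, "d2_std": 1,
        "d2_variance": 1, "d2_zero_count": 1,
        "d3_sum": 2, "d3_nonzero_min": 2, "d3_max": 2, "d3_mean": 1, "d3_std": 1,
        "d3_variance": 1, "d3_zero_count": 1,
        "avg_degree": 1.0,
    },
    G_DOUBLE: {  # edge enters at d=2; one hairpin
        "d1_sum": 0, "d1_nonzero_min": 0, "d1_variance": 0, "d1_zero_count": 2,
        "d2_sum": 2, "d2_nonzero_min": 2, "d2_max": 2, "d2_mean": 1, "d2_std": 1,
        "d2_variance": 1, "d2_zero_count": 1,
        "d3_sum": 2, "d3_nonzero_min": 2, "d3_max": 2, "d3_mean": 1, "d3_std": 1,
        "d3_variance": 1, "d3_zero_count": 1,
        "avg_degree": 0.5,
    },
    G_TRIPLE: {  # edge enters only at d=3; no hairpin
        "d1_sum": 0, "d1_nonzero_min": 0, "d1_variance": 0, "d1_zero_count": 2,
        "d2_sum": 0, "d2_nonzero_min": 0, "d2_max": 0, "d2_mean": 0, "d2_std": 0,
        "d2_variance": 0, "d2_zero_count": 2,
        "d3_sum": 2, "d3_nonzero_min": 2, "d3_max": 2, "d3_mean": 1, "d3_std": 1,
        "d3_variance": 1, "d3_zero_count": 1,
        "avg_degree": 0.0,
    },
}


def test_filtration_edge_thresholds():
    assert build_filtration(G_TRIPLE, 1).edges == ()
    assert build_filtration(G_TRIPLE, 2).edges == ()
    assert build_filtration(G_TRIPLE, 3).edges == ((0, 1),)
    assert build_filtration(G_DOUBLE, 2).edges == ((0, 1),)


def test_filtration_nested_and_final_connected(catalog5):
    """K_1 <= K_2 <= K_3, and K_3 holds every stem-stem contact."""
    for gid, g in catalog5.items():
        prev = set()
        for d in (1, 2, 3):
            K = build_filtration(g, d)
            edges = set(K.edges)
            assert prev <= edges
            prev = edges
        off = g.offdiag()
        assert prev == {
            (i, j) for i in range(g.n) for j in range(i + 1, g.n) if off[i, j]
        }


def test_clique_completion():
    tri = DualGraph([[0, 1, 1], [1, 0, 1], [1, 1, 0]], validate=False)
    K = build_filtration(tri, 1)
    assert K.triangles == ((0, 1, 2),)
    k4 = DualGraph(np.ones((4, 4), dtype=int) - np.eye(4, dtype=int), validate=False)
    K4 = build_filtration(k4, 1)
    assert len(K4.triangles) == 4 and K4.tetrahedra == ((0, 1, 2, 3),)


def test_boundary_of_boundary_vanishes(catalog5):
    for gid, g in list(catalog5.items())[::5]:
        K = build_filtration(g, 3)
        for q in (1, 2, 3):
            Bq = boundary_matrix(K, q)
            Bq1 = boundary_matrix(K, q + 1) if q < 3 else None
            if Bq1 is not None and Bq.size and Bq1.size:
                assert np.allclose(Bq @ Bq1, 0)


def test_persistent_laplacian_hand_examples():
    path3 = DualGraph([[0, 1, 0], [1, 0, 1], [0, 1, 0]], validate=False)
    ev = spectrum(persistent_laplacian(build_filtration(path3, 1), 0)).eigenvalues
    assert np.allclose(ev, [0, 1, 3])
    # filled triangle: L_1 = 3*I, no 1-cycles survive
    tri = DualGraph([[0, 1, 1], [1, 0, 1], [1, 1, 0]], validate=False)
    res = spectrum(persistent_laplacian(build_filtration(tri, 1), 1))
    assert np.allclose(res.eigenvalues, [3, 3, 3]) and res.betti == 0
    # empty edge set -> zero matrix
    L = persistent_laplacian(build_filtration(G_TRIPLE, 1), 0)
    assert np.array_equal(L, np.zeros((2, 2)))


def test_spectrum_contract():
    res = spectrum(np.zeros((2, 2)))
    assert res.betti == 2
    res = spectrum(np.array([[1.0, -1.0], [-1.0, 1.0]]))
    assert np.allclose(res.eigenvalues, [0, 2]) and res.betti == 1
    with pytest.raises(InputError):
        spectrum(np.array([[0.0, 1.0], [2.0, 0.0]]))


def test_feature_vectors_match_hand_computation():
    for g, want in HAND.items():
        got = psg_features(g)
        assert set(got) == set(FEATURE_NAMES)
        for k, v in want.items():
            assert got[k] == pytest.approx(v), k


def test_feature_invariants_across_catalog(catalog5):
    feats = featurize_catalog(catalog5)
    # Betti-0 monotone under the growing complex; connected by d=3
    assert (feats["d1_zero_count"] >= feats["d2_zero_count"]).all()
    assert (feats["d2_zero_count"] >= feats["d3_zero_count"]).all()
    assert (feats["d3_zero_count"] == 1).all()
    assert np.allclose(feats["d2_variance"], feats["d2_std"] ** 2)
    assert np.allclose(feats["d3_variance"], feats["d3_std"] ** 2)
    assert np.isfinite(feats.values).all()


def test_trace_identity_and_component_oracle(catalog5):
    """Trace of L_0 = 2 * edge count; kernel dim = union-find components."""

    def components(n, edges):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in edges:
            parent[find(i)] = find(j)
        return len({find(v) for v in range(n)})

    for gid, g in list(catalog5.items())[::3]:
        for d in (1, 2, 3):
            K = build_filtration(g, d)
            res = spectrum(persistent_laplacian(K, 0))
            assert res.eigenvalues.sum() == pytest.approx(2 * len(K.edges))
            assert res.betti == components(g.n, K.edges)


def test_avg_degree_counts_hairpins(catalog5):
    for gid, g in list(catalog5.items())[::10]:
        assert psg_features(g)["avg_degree"] == pytest.approx(g.loop_count / g.n)


def test_featurize_catalog_table(catalog5, tmp_path):
    from ragspace.io import read_features, write_features

    feats = featurize_catalog(catalog5)
    assert feats.shape == (len(catalog5), 19)
    assert list(feats.columns) == list(FEATURE_NAMES)
    row = feats.loc["2_3"]
    assert row.to_dict() == pytest.approx(psg_features(G_TRIPLE))
    path = write_features(feats, tmp_path / "f.tsv")
    assert read_features(path).equals(feats)


def test_featurizer_transformer(catalog5):
    est = PSGFeaturizer()
    X = est.fit_transform([G_SINGLE, G_DOUBLE, G_TRIPLE])
    assert X.shape == (3, 19)
    assert X[2].tolist() == [psg_features(G_TRIPLE)[k] for k in FEATURE_NAMES]
    assert est.get_params()["include_zeros"] is True


def test_exclude_zero_eigenvalues_flag():
    got = psg_features(G_TRIPLE, include_zeros=False)
    # d=3 spectrum {0, 2}: mean over nonzero only
    assert got["d3_mean"] == pytest.approx(2.0)
    assert got["d3_variance"] == pytest.approx(0.0)
    assert got["d3_zero_count"] == 1  # unchanged
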