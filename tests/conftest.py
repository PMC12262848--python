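import numpy as np
import pytest

from ragspace import DualGraph, build_catalog, featurize_catalog

# the three 2-vertex topologies (single/double/triple edge, loops filling
# the degree-sum rule) — the smallest complete catalog, used everywhere
G_SINGLE = DualGraph([[2, 1], [1, 2]])   # 2_1: one strand, two hairpins
G_DOUBLE = DualGraph([[2, 2], [2, 0]])   # 2_2: internal-loop-like double edge
G_TRIPLE = DualGraph([[0, 3], [3, 0]])   # 2_3: pseudoknot-like triple edge


@pytest.fixture(scope="session")
def catalog6():
    """Full catalog for 2..6 vertices (3+8+29+110+508 topologies)."""
    return build_catalog(2, 6)


@pytest.fixture(scope="session")
def catalog5(catalog6):
    return catalog6.subset(range(2, 6))


@pytest.fixture(scope="session")
def features6(catalog6):
    return featurize_catalog(catalog6)


@pytest.fixture(scope="session")
def catalog7(catalog6):
    """Catalog through 7 vertices (desk-scale ceiling; ~25 s to build)."""
    from ragspace import enumerate_dual_graphs

    return catalog6.merged(enumerate_dual_graphs(7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
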