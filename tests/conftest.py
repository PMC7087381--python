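import numpy as np
import pytest

from isosim.data_io import (
    GeneIsoformSet,
    IsoformCountMatrix,
    IsoformStats,
    compute_isoform_stats,
    select_four_isoform_genes,
)
from isosim.synthetic_data import SyntheticSpec, generate_counts


@pytest.fixture(scope="session")
def fixture_spec():
    """Default 50-gene x 100-cell study fixture."""
    return SyntheticSpec(n_genes=50, n_cells=100, K_M_true=10.0, seed=20240)


@pytest.fixture(scope="session")
def fixture_data(fixture_spec):
    return generate_counts(fixture_spec)


@pytest.fixture(scope="session")
def fixture_matrix(fixture_data):
    return fixture_data[0]


@pytest.fixture(scope="session")
def fixture_truth(fixture_data):
    return fixture_data[1]


@pytest.fixture(scope="session")
def fixture_genes(fixture_matrix):
    genes = select_four_isoform_genes(fixture_matrix)
    assert genes, "fixture must yield four-isoform genes"
    return genes


@pytest.fixture(scope="session")
def fixture_stats(fixture_matrix):
    return compute_isoform_stats(fixture_matrix)


@pytest.fixture
def toy_matrix():
    """Hand-built matrix: gene A has 4 detected + 1 failing isoform, gene B has 5 detected."""
    isoforms = [f"A.{k}" for k in range(1, 6)] + [f"B.{k}" for k in range(1, 6)]
    counts = np.array([
        [60, 60, 60],   # A.1 detected
        [40, 40, 0],    # A.2 detected
        [20, 20, 0],    # A.3 detected
        [10, 10, 0],    # A.4 detected
        [5, 5, 5],      # A.5 NOT detected (never strictly > 5)
        [60, 60, 60],   # B.1..B.5 all detected
        [50, 50, 0],
        [40, 40, 0],
        [30, 30, 0],
        [20, 20, 0],
    ])
    gene_of = {t: t.split(".")[0] for t in isoforms}
    return IsoformCountMatrix(isoforms, ["c1", "c2", "c3"], counts, gene_of)


@pytest.fixture
def interior_gene():
    """A gene whose isoforms have interior detection probabilities, so the
    inferred-probability machinery is exercised away from its clamps."""
    gene = GeneIsoformSet("G1", ("a", "b", "c", "d"))
    p_det = [0.6, 0.45, 0.3, 0.15]
    stats = {
        t: IsoformStats(S=100.0, p_detection=p, dropout_rate=1 - p, total_counts=100)
        for t, p in zip(gene.isoforms, p_det)
    }
    dropout = np.array([0.3, 0.45, 0.6, 0.8])
    return gene, stats, dropout
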