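import numpy as np
import pytest
from scipy import sparse

from orthotype import (
    CellAnnotation,
    CountMatrix,
    SimConfig,
    simulate_atlas_pair,
)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study conditions for fast unit tests.

    The baseline mean is raised so per-cell totals stay above the default
    200-UMI QC threshold despite the smaller gene complement.
    """
    return SimConfig(
        n_orthogroups=400,
        n_shared_families=6,
        n_private_s1=1,
        n_private_s2=1,
        cells_per_type=60,
        baseline_mean=0.8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_atlas(small_config):
    data, truth = simulate_atlas_pair(small_config)
    return data, truth


@pytest.fixture()
def qc_toy():
    """12-cell toy matrix embedding exactly one <200-UMI cell, one
    >10%-mito cell and one gene detected in only 4 cells.

    Genes: G1..G5 broadly expressed, RARE in exactly 4 cells, MT1 the
    mitochondrial gene.  Cell 'low' totals 150 UMIs; cell 'mito' has 12%
    mitochondrial UMIs; all other cells total >= 200 with ~2% mito.
    """
    genes = ["G1", "G2", "G3", "G4", "G5", "RARE", "MT1"]
    cells = [f"c{i + 1:02d}" for i in range(12)]
    mat = np.zeros((7, 12), dtype=np.int64)
    # ten ordinary cells: 60 each of G1..G4, 10 of G5, 6 of MT1 -> 256 UMIs, 2.3% mito
    for j in range(10):
        mat[0:4, j] = 60
        mat[4, j] = 10
        mat[6, j] = 6
    # RARE detected in exactly 4 ordinary cells, one count each
    mat[5, 0:4] = 1
    # cell 11 ("low"): 150 UMIs, low mito
    mat[0:4, 10] = 36
    mat[4, 10] = 3
    mat[6, 10] = 3  # 150 total, 2% mito
    # cell 12 ("mito"): 250 UMIs with 30 mito -> 12%
    mat[0:4, 11] = 52
    mat[4, 11] = 12
    mat[6, 11] = 30
    cm = CountMatrix(sparse.csr_matrix(mat), genes, cells, "toy")
    return cm, {"low": "c11", "mito": "c12", "rare_gene": "RARE"}


@pytest.fixture()
def tiny_annotation():
    def make(cell_ids, labels):
        return CellAnnotation.from_labels(cell_ids, labels)

    return make
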