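import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from repact import CohortConfig, FeatureMatrix, generate_cohort, generate_toy_regulome
from repact.io import CellTable


@pytest.fixture(scope="session")
def small_cohort():
    """A small but signal-bearing cohort shared across read-only tests."""
    cfg = CohortConfig(
        n_donors_healthy=3,
        n_donors_disease=3,
        cells_per_donor=200,
        n_genes=600,
        n_peaks=600,
        n_intra_features=60,
        n_inter_features=60,
        seed=11,
    )
    return cfg, *generate_cohort(cfg)


@pytest.fixture(scope="session")
def toy_regulome():
    return generate_toy_regulome(n_genes=20, n_peaks=60, n_loops=15, seed=5)


@pytest.fixture()
def tiny_matrix():
    counts = np.array([[5, 0, 1], [0, 3, 2], [4, 4, 0], [1, 0, 7]])
    return FeatureMatrix(
        sp.csr_matrix(counts), [f"c{i}" for i in range(4)], ["g1", "g2", "g3"], "gene"
    )


@pytest.fixture()
def tiny_cells():
    return CellTable(
        pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(4)],
                "donor_id": ["d1", "d1", "d2", "d2"],
                "phenotype": ["healthy", "healthy", "T2D", "T2D"],
            }
        )
    )
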