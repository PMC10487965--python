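import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from mitostate import CountMatrix, SimulationConfig, simulate
from mitostate.synthetic_data import CascadeSpec


@pytest.fixture(scope="session")
def default_sim():
    """One draw under the default study conditions (3 cell types, 2x4 samples)."""
    return simulate(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def cdpc_sim():
    """Single-cell-type draw used by the state-discovery tests."""
    cfg = SimulationConfig(
        seed=42,
        cell_types=("CD-PC",),
        doublet_fraction=0.0,
        cascade=CascadeSpec(source_cell_type="CD-PC", target_cell_type="CD-PC"),
    )
    return simulate(cfg)


def toy_count_matrix(counts, gene_ids=None, groups=None, cell_types=None):
    """Small CountMatrix with minimal metadata for unit tests."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_ids = gene_ids or [f"G{i}" for i in range(n_genes)]
    cell_ids = [f"C{i}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "sample_id": ["s1"] * n_cells,
            "group": groups or ["Ctrl"] * n_cells,
            "cell_type": cell_types or ["CD-PC"] * n_cells,
        },
        index=pd.Index(cell_ids, name="barcode"),
    )
    return CountMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=np.asarray(gene_ids, dtype=object),
        cell_ids=np.asarray(cell_ids, dtype=object),
        cell_meta=meta,
    )
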