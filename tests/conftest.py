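import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scmetgrade import (
    CountMatrix,
    GeneSetCollection,
    ScSimConfig,
    default_geneset_collection,
    sim_sc_dataset,
)


@pytest.fixture(scope="session")
def small_gs() -> GeneSetCollection:
    return default_geneset_collection(n_pathways=6, genes_per_pathway=5, overlap_every=3)


@pytest.fixture(scope="session")
def sc_small(small_gs):
    """Small simulated dataset: 4 cell types x 60 cells per condition."""
    cfg = ScSimConfig(
        genesets=small_gs,
        n_cell_types=4,
        cells_per_type_per_condition=60,
        n_genes=max(80, len(small_gs.universe)),
        seed=11,
    )
    return sim_sc_dataset(cfg)


def make_count_matrix(dense, gene_ids=None, cell_ids=None) -> CountMatrix:
    dense = np.asarray(dense)
    n_genes, n_cells = dense.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    cell_ids = cell_ids or [f"c{i}" for i in range(n_cells)]
    return CountMatrix(sp.csr_matrix(dense), gene_ids, cell_ids)


def make_meta(cell_ids, conditions, cell_types, samples=None) -> pd.DataFrame:
    meta = pd.DataFrame(
        {
            "cell_id": list(cell_ids),
            "sample_id": samples if samples is not None else ["S1"] * len(cell_ids),
            "condition": list(conditions),
            "cell_type": list(cell_types),
        }
    )
    return meta.set_index("cell_id", drop=False)
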