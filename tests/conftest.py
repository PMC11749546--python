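import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scprograms import CountMatrix


def make_count_matrix(
    counts,
    gene_ids=None,
    cell_ids=None,
    sample_id="S1",
    organ="uterus",
    group="estrogen",
    cell_type="epithelial",
    groups=None,
):
    """CountMatrix from a dense array with auto-generated ids/metadata."""
    counts = np.asarray(counts, dtype=np.int64)
    n_genes, n_cells = counts.shape
    gene_ids = gene_ids or [f"G{i + 1:03d}" for i in range(n_genes)]
    cell_ids = cell_ids or [f"C{i + 1:03d}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "sample_id": sample_id,
            "organ": organ,
            "group": groups if groups is not None else group,
            "cell_type": cell_type,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return CountMatrix(gene_ids, cell_ids, sp.csr_matrix(counts), meta)


@pytest.fixture
def tiny_matrix():
    """3 genes x 2 cells with 4 stored entries."""
    return make_count_matrix([[1, 0], [2, 3], [0, 4]])


@pytest.fixture
def rng():
    return np.random.default_rng(42)
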