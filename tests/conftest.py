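import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import settings

from txnoise import CountMatrix, NormalizedMatrix, normalize

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def make_count_matrix(counts, gene_ids=None, barcodes=None, meta=None):
    """Build a valid CountMatrix from a dense array with default metadata."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    barcodes = barcodes or [f"bc{i}" for i in range(n_cells)]
    if meta is None:
        meta = pd.DataFrame(
            {
                "sample_id": "s1",
                "genotype": "WT",
                "timepoint": "2mo",
            },
            index=pd.Index(barcodes, name="barcode"),
        )
    return CountMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=np.array(gene_ids, dtype=object),
        barcodes=np.array(barcodes, dtype=object),
        cell_meta=meta,
    )


def make_normalized(values, gene_ids=None, barcodes=None):
    """Wrap a dense non-negative array directly as a NormalizedMatrix."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    barcodes = barcodes or [f"bc{i}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {"sample_id": "s1", "genotype": "WT", "timepoint": "2mo"},
        index=pd.Index(barcodes, name="barcode"),
    )
    return NormalizedMatrix(
        values=sp.csr_matrix(values),
        gene_ids=np.array(gene_ids, dtype=object),
        barcodes=np.array(barcodes, dtype=object),
        cell_meta=meta,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_counts(rng):
    """A 50-gene x 20-cell random integer matrix with ~30% zeros."""
    dense = rng.poisson(3.0, size=(50, 20))
    dense[rng.random(dense.shape) < 0.3] = 0
    return make_count_matrix(dense)


@pytest.fixture
def random_normalized(random_counts):
    return normalize(random_counts)
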