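import numpy as np
import pandas as pd
import pytest

from sclenbias.ingest import ExpressionDataset


def make_dataset(counts, gene_ids=None, symbols=None, lengths=None, classes=None,
                 curated=None, cell_ids=None, conditions=None, protocol="full_length",
                 dataset_id="toy"):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(n_genes)]
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": symbols or gene_ids,
            "length_bp": lengths if lengths is not None else [1000.0] * n_genes,
            "gene_class": classes or ["ordinary"] * n_genes,
            "curated": curated if curated is not None else [True] * n_genes,
        }
    )
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids or [f"c{i + 1}" for i in range(n_cells)],
            "dataset_id": dataset_id,
            "condition": conditions or ["unknown"] * n_cells,
            "batch": "b1",
        }
    )
    return ExpressionDataset(counts, genes, cells, protocol=protocol)


@pytest.fixture
def qc_toy():
    """Six genes x five cells with one mito, one ribo, one spike-in, one
    length-less gene and two ordinary genes; hand-enumerated QC survivors.

    With removal thresholds "dropout > 0.80" and "library < 10": cell c2
    (library 8) and c5 (all-zero) are removed. On the surviving cells
    (c1, c3, c4) the default gene policy keeps exactly g1 and g2: g3/g4 are
    excluded classes, g5 is a spike-in, g6 has no length.
    """
    counts = np.array(
        [
            [5, 0, 3, 1, 0],   # g1 ordinary, 500 bp
            [10, 2, 8, 0, 0],  # g2 ordinary, 1500 bp
            [1, 1, 1, 1, 0],   # g3 mito
            [2, 0, 2, 2, 0],   # g4 ribo
            [3, 1, 3, 3, 0],   # g5 spike-in
            [4, 4, 4, 4, 0],   # g6 ordinary, unknown length
        ]
    )
    return make_dataset(
        counts,
        gene_ids=["g1", "g2", "g3", "g4", "ERCC-00001", "g6"],
        symbols=["Actb", "Nanog", "mt-Nd1", "Rpl13a", "ERCC-00001", "Pou5f1"],
        lengths=[500.0, 1500.0, 900.0, 700.0, 800.0, np.nan],
        classes=["ordinary", "ordinary", "mito", "ribo", "spikein", "ordinary"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
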