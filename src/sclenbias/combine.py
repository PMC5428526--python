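"""Combining datasets on commonly detected genes and comparing detection
between protocol groups.

A gene counts as *detected* in a dataset when it has a nonzero count in at
least ``ceil(min_cell_fraction * n_cells)`` cells.  Intersecting per-dataset
detected sets before combining keeps large datasets from dominating gene
selection; the union of the per-dataset detected sets defines the universe
for the protocol-group Venn comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bias import log_cpm
from .ingest import ExpressionDataset

logger = logging.getLogger(__name__)


def detected_gene_set(dataset: ExpressionDataset,
                      min_cell_fraction: float = 0.10) -> set[str]:
    """Genes with a nonzero count in at least the given fraction of cells.

    The cell-count threshold is ``ceil(min_cell_fraction * n_cells)``, so
    the criterion reads "at least"; a fraction of 0 admits every gene.
    """
    threshold = math.ceil(min_cell_fraction * dataset.n_cells)
    n_nonzero = (dataset.counts > 0).sum(axis=1)
    mask = n_nonzero >= threshold
    return set(dataset.genes.loc[mask, "gene_id"])


def common_genes(datasets: list[ExpressionDataset],
                 min_cell_fraction: float = 0.10) -> list[str]:
    """Genes detected in every dataset, ordered lexicographically."""
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")
    shared = set.intersection(
        *(detected_gene_set(d, min_cell_fraction) for d in datasets)
    )
    if not shared:
        logger.warning("no genes commonly detected across %d datasets", len(datasets))
    return sorted(shared)


def combine_datasets(datasets: list[ExpressionDataset],
                     genes: list[str]) -> ExpressionDataset:
    """Column-concatenate datasets restricted to a shared ordered gene list.

    Every gene must be present in every dataset.  Cell records keep their
    ``dataset_id`` and gain a ``protocol`` column recording the source
    protocol per cell; the combined dataset's own protocol tag is
    ``full_length`` if any source is (the tag is per-cell where it matters).
    """
    blocks = []
    cell_tables = []
    gene_table = None
    for ds in datasets:
        index = pd.Index(ds.genes["gene_id"])
        missing = [g for g in genes if g not in index]
        if missing:
            raise ValueError(
                f"gene(s) missing from dataset {ds.provenance or '?'}: {missing[:5]}"
            )
        rows = index.get_indexer(genes)
        blocks.append(ds.counts[rows, :])
        cells = ds.cells.copy()
        cells["protocol"] = ds.protocol
        cell_tables.append(cells)
        if gene_table is None:
            gene_table = ds.genes.iloc[rows].reset_index(drop=True)
    combined = ExpressionDataset(
        counts=np.hstack(blocks),
        genes=gene_table,
        cells=pd.concat(cell_tables, ignore_index=True),
        protocol=datasets[0].protocol,
        provenance=f"combined:{len(datasets)} datasets on {len(genes)} shared genes",
    )
    return combined


def pca_embedding(log_expr: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of a cells x genes expression matrix via SVD of the centered matrix.

    Returns ``(coordinates, variances, loadings)`` where coordinates is
    cells x n_components, variances are the component variances sorted
    non-increasing, and loadings is n_components x genes.  The sign of each
    component is fixed so its largest-magnitude gene loading is positive.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    X = np.asarray(log_expr, dtype=float)
    n_cells, n_genes = X.shape
    if n_components > min(n_cells, n_genes):
        raise ValueError("n_components exceeds min(cells, genes)")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    for i in range(n_components):
        peak = np.argmax(np.abs(Vt[i]))
        if Vt[i, peak] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    coords = U * S
    variances = S**2 / max(n_cells - 1, 1)
    return coords, variances, Vt


def combined_log_expression(combined: ExpressionDataset,
                            pseudocount: float = 1.0) -> np.ndarray:
    """Cells x genes log2(CPM+pseudocount) matrix for embedding.

    CPM is computed per cell over the shared genes only; no batch
    correction is applied, so dataset of origin typically dominates the
    first component.
    """
    return log_cpm(combined.counts, pseudocount=pseudocount).T


@dataclass
class DetectionOverlap:
    """Venn regions of two protocol groups' detected-gene sets.

    A group's detected set is the *intersection* of its member datasets'
    detected sets (detected in every dataset of the group); the universe is
    the union of all per-dataset detected sets.
    """

    universe_size: int
    in_both: int
    only_group_a: int
    only_group_b: int
    members_in_both: list[str] = field(default_factory=list)
    members_only_a: list[str] = field(default_factory=list)
    members_only_b: list[str] = field(default_factory=list)
    group_a_size: int = 0
    group_b_size: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Long-format gene_id/region table for writing as TSV."""
        rows = (
            [(g, "both") for g in self.members_in_both]
            + [(g, "only_a") for g in self.members_only_a]
            + [(g, "only_b") for g in self.members_only_b]
        )
        return pd.DataFrame(rows, columns=["gene_id", "region"])


def detection_overlap(group_a: list[ExpressionDataset],
                      group_b: list[ExpressionDataset],
                      min_cell_fraction: float = 0.10) -> DetectionOverlap:
    """Compare genes detected in every dataset of group A vs group B."""
    if not group_a or not group_b:
        raise ValueError("each group needs at least one dataset")
    sets_a = [detected_gene_set(d, min_cell_fraction) for d in group_a]
    sets_b = [detected_gene_set(d, min_cell_fraction) for d in group_b]
    set_a = set.intersection(*sets_a)
    set_b = set.intersection(*sets_b)
    universe = set.union(*sets_a, *sets_b)
    both = set_a & set_b
    only_a = set_a - set_b
    only_b = set_b - set_a
    return DetectionOverlap(
        universe_size=len(universe),
        in_both=len(both),
        only_group_a=len(only_a),
        only_group_b=len(only_b),
        members_in_both=sorted(both),
        members_only_a=sorted(only_a),
        members_only_b=sorted(only_b),
        group_a_size=len(set_a),
        group_b_size=len(set_b),
    )
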