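"""Per-cell quality metrics and cell/gene filtering.

Every threshold is phrased as a removal condition on the metric ("more
than", "fewer than"), so a cell or gene that sits exactly on a threshold is
retained: ``filter_cells`` keeps cells with dropout <= max_dropout, library
size >= min_library_size and (when capped) spike-in fraction <=
max_spikein_fraction.

Per-cell dropout is computed over all matrix rows before gene filtering;
per-gene zero fractions are computed over the cells that survive cell
filtering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level retention thresholds.

    ``max_dropout`` and ``max_spikein_fraction`` are fractions in [0, 1];
    ``min_library_size`` is in counts. ``max_spikein_fraction=None`` disables
    the spike-in cap (for datasets without spike-ins).
    """

    max_dropout: float = 1.0
    min_library_size: float = 0.0
    max_spikein_fraction: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.max_dropout <= 1.0:
            raise ValueError("max_dropout must be in [0, 1]")
        if self.min_library_size < 0:
            raise ValueError("min_library_size must be non-negative")
        if self.max_spikein_fraction is not None and not (
            0.0 <= self.max_spikein_fraction <= 1.0
        ):
            raise ValueError("max_spikein_fraction must be in [0, 1]")


#: Published per-dataset cell-QC profiles, keyed by first author of the
#: source study.  ``None`` means no cell filtering was applied (all cells
#: passed visual QC).  The Kolodziejczyk profile additionally involved a
#: plate-level spike-in review with no numeric criterion; see
#: :func:`batch_spikein_summary`.
THRESHOLD_PRESETS: dict[str, QCThresholds | None] = {
    "kolodziejczyk": QCThresholds(0.80, 500_000, None),
    "guo": QCThresholds(0.85, 500_000, None),
    "camp": QCThresholds(0.90, 500_000, 0.20),
    "grun": QCThresholds(0.80, 10_000, 0.05),
    "tung": QCThresholds(0.70, 30_000, 0.03),
    "klein": QCThresholds(0.85, 10_000, 0.01),
    "ziegenhain": None,
    "buettner": QCThresholds(0.85, 1_000_000, None),
}


@dataclass(frozen=True)
class GeneFilterPolicy:
    """Gene retention policy.

    Genes are removed when their zero fraction exceeds ``max_zero_fraction``
    (default: more than 90% zeroes), when their class is excluded
    (mitochondrial/ribosomal by default; spike-ins are always dropped from
    the analysis matrix), when they lack a curated identifier, or when their
    length is unknown.
    """

    max_zero_fraction: float = 0.90
    excluded_classes: frozenset = frozenset({"mito", "ribo"})
    require_curated: bool = True
    require_length: bool = True

    def __post_init__(self):
        if not 0.0 <= self.max_zero_fraction <= 1.0:
            raise ValueError("max_zero_fraction must be in [0, 1]")
        object.__setattr__(self, "excluded_classes", frozenset(self.excluded_classes))


def compute_cell_metrics(dataset: ExpressionDataset) -> pd.DataFrame:
    """Per-cell dropout fraction, library size, and spike-in read fraction.

    Dropout is the share of matrix rows (spike-ins included) with a zero
    count; library size is the column sum; the spike-in fraction of an
    all-zero cell is defined as 0.
    """
    counts = dataset.counts
    n_genes = counts.shape[0]
    library = counts.sum(axis=0)
    dropout = (counts == 0).sum(axis=0) / n_genes if n_genes else np.ones(counts.shape[1])
    spike_rows = (dataset.genes["gene_class"] == "spikein").to_numpy()
    spike_counts = counts[spike_rows, :].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        spike_frac = np.where(library > 0, spike_counts / np.maximum(library, 1), 0.0)
    return pd.DataFrame(
        {
            "cell_id": dataset.cells["cell_id"].to_numpy(),
            "dropout_fraction": dropout,
            "library_size": library.astype(np.int64),
            "spikein_fraction": spike_frac,
        }
    )


def filter_cells(
    dataset: ExpressionDataset, thresholds: QCThresholds | None
) -> ExpressionDataset:
    """Retain cells that violate none of the removal thresholds.

    ``thresholds=None`` is the identity (datasets whose cells all passed
    QC upstream). Removing every cell yields a valid empty dataset and a
    logged warning.
    """
    if thresholds is None:
        return dataset
    metrics = compute_cell_metrics(dataset)
    keep = (metrics["dropout_fraction"] <= thresholds.max_dropout) & (
        metrics["library_size"] >= thresholds.min_library_size
    )
    if thresholds.max_spikein_fraction is not None:
        keep &= metrics["spikein_fraction"] <= thresholds.max_spikein_fraction
    keep = keep.to_numpy()
    if not keep.any():
        logger.warning("cell filtering removed all %d cells", dataset.n_cells)
    return dataset.subset_cells(keep)


def gene_zero_fraction(dataset: ExpressionDataset) -> np.ndarray:
    """Share of cells with a zero count, per gene (1.0 if there are no cells)."""
    if dataset.n_cells == 0:
        return np.ones(dataset.n_genes)
    return (dataset.counts == 0).sum(axis=1) / dataset.n_cells


def filter_genes(
    dataset: ExpressionDataset, policy: GeneFilterPolicy | None = None
) -> ExpressionDataset:
    """Apply the gene filter policy; call after cell filtering.

    Spike-in rows are always removed from the analysis matrix (they are
    controls, not genes) but their count is recorded in the provenance
    string of the returned dataset.
    """
    policy = policy or GeneFilterPolicy()
    keep = _gene_keep_mask(dataset, policy)
    n_spike = int((dataset.genes["gene_class"] == "spikein").sum())
    out = dataset.subset_genes(keep)
    out.provenance = (
        dataset.provenance + f" [gene filter: kept {int(keep.sum())}/{dataset.n_genes}; "
        f"{n_spike} spike-in rows removed]"
    ).strip()
    return out


def _gene_keep_mask(dataset: ExpressionDataset, policy: GeneFilterPolicy) -> np.ndarray:
    zero_frac = gene_zero_fraction(dataset)
    genes = dataset.genes
    keep = zero_frac <= policy.max_zero_fraction
    keep &= ~genes["gene_class"].isin(policy.excluded_classes).to_numpy()
    keep &= (genes["gene_class"] != "spikein").to_numpy()
    if policy.require_curated:
        keep &= genes["curated"].to_numpy().astype(bool)
    if policy.require_length:
        keep &= genes["length_bp"].notna().to_numpy()
    return keep


def qc_report(before: ExpressionDataset, after: ExpressionDataset,
              policy: GeneFilterPolicy | None = None) -> pd.DataFrame:
    """Summary of what cell+gene filtering removed, per criterion.

    *before* is the raw dataset, *after* the fully filtered one. Per-criterion
    gene counts are evaluated on the cell-filtered matrix (the same matrix the
    gene filter saw), so overlapping criteria may sum to more than the total
    removed.
    """
    policy = policy or GeneFilterPolicy()
    kept_cells = set(after.cells["cell_id"])
    cell_filtered = before.subset_cells(
        before.cells["cell_id"].isin(kept_cells).to_numpy()
    )
    zero_frac = gene_zero_fraction(cell_filtered)
    genes = cell_filtered.genes
    rows = [
        ("cells_before", before.n_cells),
        ("cells_retained", after.n_cells),
        ("cells_removed", before.n_cells - after.n_cells),
        ("genes_before", before.n_genes),
        ("genes_retained", after.n_genes),
        ("genes_removed", before.n_genes - after.n_genes),
        ("genes_removed_zero_fraction",
         int((zero_frac > policy.max_zero_fraction).sum())),
        ("genes_removed_class",
         int(genes["gene_class"].isin(policy.excluded_classes).sum())),
        ("genes_removed_spikein", int((genes["gene_class"] == "spikein").sum())),
        ("genes_removed_noncurated",
         int((~genes["curated"].astype(bool)).sum()) if policy.require_curated else 0),
        ("genes_removed_no_length",
         int(genes["length_bp"].isna().sum()) if policy.require_length else 0),
    ]
    return pd.DataFrame(rows, columns=["criterion", "count"])


def write_qc_report(report: pd.DataFrame, out_dir) -> None:
    """Write the QC report as both TSV and JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.to_csv(out_dir / "qc_report.tsv", sep="\t", index=False)
    with open(out_dir / "qc_report.json", "w") as fh:
        json.dump(dict(zip(report["criterion"], report["count"].astype(int))), fh,
                  indent=2)
        fh.write("\n")


def batch_spikein_summary(dataset: ExpressionDataset) -> pd.DataFrame:
    """Median spike-in fraction per batch, for analyst review.

    Plate-level exclusion (batches with excessive spike-in content) is a
    judgement call with no published numeric rule, so this table supports a
    manual decision rather than automating one.
    """
    metrics = compute_cell_metrics(dataset)
    metrics["batch"] = dataset.cells["batch"].to_numpy()
    grouped = metrics.groupby("batch", sort=True)["spikein_fraction"]
    return (
        grouped.agg(["count", "median", "mean", "max"])
        .reset_index()
        .rename(columns={"count": "n_cells"})
    )
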