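"""Reading and writing count matrices, gene annotation, and gene lengths.

The central container is :class:`ExpressionDataset`: a genes x cells matrix of
non-negative integer counts together with aligned gene and cell annotation
tables and a protocol tag (``full_length`` or ``umi``).

Gene lengths are union-exon lengths: the number of genomic bases covered by
any exon of the gene after merging overlapping intervals across all
transcripts (strand ignored), which is the "Length" a gene-level read counter
reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

GENE_CLASSES = ("ordinary", "mito", "ribo", "spikein")

GENE_COLUMNS = ["gene_id", "symbol", "length_bp", "gene_class", "curated"]
CELL_COLUMNS = ["cell_id", "dataset_id", "condition", "batch"]

#: Default recognition rules: identifier prefix for spike-ins, symbol
#: prefixes for mitochondrial and ribosomal-protein genes (mouse and human
#: nomenclature).  Precedence: spikein > mito > ribo.
DEFAULT_CLASS_PATTERNS = {
    "spikein_id_prefix": ("ERCC-",),
    "mito_symbol_prefix": ("mt-", "MT-", "Mt-"),
    "ribo_symbol_prefix": ("Rps", "Rpl", "RPS", "RPL"),
}


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class ExpressionDataset:
    """A gene-by-cell count matrix with aligned annotation.

    Parameters
    ----------
    counts
        ``(n_genes, n_cells)`` array of non-negative integer counts.
    genes
        DataFrame aligned to rows, with columns ``gene_id``, ``symbol``,
        ``length_bp`` (NaN when unknown), ``gene_class``, ``curated``.
    cells
        DataFrame aligned to columns, with columns ``cell_id``,
        ``dataset_id``, ``condition``, ``batch``.
    protocol
        ``"full_length"`` or ``"umi"``.
    provenance
        Free-text description of where the data came from.
    """

    counts: np.ndarray
    genes: pd.DataFrame
    cells: pd.DataFrame
    protocol: str = "full_length"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                bad = np.argwhere(as_int != self.counts)[0]
                raise FormatError(
                    f"non-integer count at gene row {bad[0]}, cell column {bad[1]}"
                )
            self.counts = as_int
        if self.counts.size and self.counts.min() < 0:
            bad = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at gene row {bad[0]}, cell column {bad[1]}"
            )
        if len(self.genes) != self.counts.shape[0]:
            raise ValueError(
                f"gene table has {len(self.genes)} rows but matrix has "
                f"{self.counts.shape[0]}"
            )
        if len(self.cells) != self.counts.shape[1]:
            raise ValueError(
                f"cell table has {len(self.cells)} rows but matrix has "
                f"{self.counts.shape[1]} columns"
            )
        if self.protocol not in ("full_length", "umi"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        self.genes = self.genes.reset_index(drop=True)
        self.cells = self.cells.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, mask_or_index) -> "ExpressionDataset":
        """Return a new dataset restricted to the given gene rows (order kept)."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionDataset(
            counts=self.counts[idx, :],
            genes=self.genes.iloc[idx].reset_index(drop=True),
            cells=self.cells,
            protocol=self.protocol,
            provenance=self.provenance,
        )

    def subset_cells(self, mask_or_index) -> "ExpressionDataset":
        """Return a new dataset restricted to the given cell columns (order kept)."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionDataset(
            counts=self.counts[:, idx],
            genes=self.genes,
            cells=self.cells.iloc[idx].reset_index(drop=True),
            protocol=self.protocol,
            provenance=self.provenance,
        )


def _default_gene_table(gene_ids) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "symbol": list(gene_ids),
            "length_bp": np.nan,
            "gene_class": "ordinary",
            "curated": True,
        }
    )


def _default_cell_table(cell_ids) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": list(cell_ids),
            "dataset_id": "unknown",
            "condition": "unknown",
            "batch": "unknown",
        }
    )


def _read_annotation(path: Path, kind: str) -> pd.DataFrame:
    """Read a gene or cell annotation TSV, or a bare one-id-per-line file."""
    with open(path) as fh:
        first = fh.readline()
    id_col = "gene_id" if kind == "gene" else "cell_id"
    if "\t" in first or first.strip() == id_col:
        df = pd.read_csv(path, sep="\t", dtype={id_col: str})
        if id_col not in df.columns:
            raise FormatError(f"{path}: missing required column {id_col!r}")
        if kind == "gene":
            for col, default in (
                ("symbol", df[id_col]),
                ("length_bp", np.nan),
                ("gene_class", "ordinary"),
                ("curated", True),
            ):
                if col not in df.columns:
                    df[col] = default
            df["curated"] = df["curated"].astype(bool)
            df["length_bp"] = pd.to_numeric(df["length_bp"], errors="coerce")
        else:
            for col in ("dataset_id", "condition", "batch"):
                if col not in df.columns:
                    df[col] = "unknown"
        return df
    ids = [line.strip() for line in open(path) if line.strip()]
    return _default_gene_table(ids) if kind == "gene" else _default_cell_table(ids)


def _sibling(path: Path, names: tuple[str, ...]) -> Path:
    for name in names:
        cand = path.parent / name
        if cand.exists():
            return cand
    raise FileNotFoundError(
        f"no sibling annotation file next to {path} (looked for {', '.join(names)})"
    )


def read_count_matrix(
    path,
    format: str = "mtx_triplet",
    protocol: str = "full_length",
) -> ExpressionDataset:
    """Read a count matrix with its gene/cell annotation.

    ``mtx_triplet``: *path* is a MatrixMarket coordinate file; gene and cell
    annotation are read from sibling files ``genes.tsv``/``genes.txt`` and
    ``cells.tsv``/``cells.txt`` in the same directory (TSV tables or bare
    id-per-line lists).  ``tsv_dense``: *path* is a dense TSV whose first
    column holds gene ids and whose header row holds cell ids.

    Counts must be non-negative integers; violations raise
    :class:`FormatError` naming the offending coordinate.
    """
    path = Path(path)
    if format == "mtx_triplet":
        if path.is_dir():
            path = path / "matrix.mtx"
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = _read_annotation(_sibling(path, ("genes.tsv", "genes.txt")), "gene")
        cells = _read_annotation(_sibling(path, ("cells.tsv", "cells.txt")), "cell")
        if len(genes) != mat.shape[0] or len(cells) != mat.shape[1]:
            raise FormatError(
                f"matrix is {mat.shape[0]}x{mat.shape[1]} but annotation lists "
                f"{len(genes)} genes and {len(cells)} cells"
            )
        return ExpressionDataset(mat, genes, cells, protocol=protocol,
                                 provenance=str(path))
    if format == "tsv_dense":
        df = pd.read_csv(path, sep="\t", index_col=0)
        genes = _default_gene_table(df.index.astype(str))
        cells = _default_cell_table(df.columns.astype(str))
        return ExpressionDataset(df.to_numpy(), genes, cells, protocol=protocol,
                                 provenance=str(path))
    raise ValueError(f"unknown format {format!r}")


def write_dataset(dataset: ExpressionDataset, out_dir) -> dict[str, Path]:
    """Write *dataset* as ``matrix.mtx`` + ``genes.tsv`` + ``cells.tsv``.

    The output round-trips exactly through :func:`read_count_matrix`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "genes": out_dir / "genes.tsv",
        "cells": out_dir / "cells.tsv",
    }
    sparse = scipy.sparse.coo_matrix(dataset.counts)
    scipy.io.mmwrite(str(paths["matrix"]), sparse, field="integer")
    dataset.genes[GENE_COLUMNS].to_csv(paths["genes"], sep="\t", index=False)
    dataset.cells[CELL_COLUMNS].to_csv(paths["cells"], sep="\t", index=False)
    return paths


_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


def union_exon_lengths(gtf_path) -> dict[str, int]:
    """Union-exon length per gene from a GTF file.

    Exon intervals of each gene are merged across transcripts (strand
    ignored) and the merged interval lengths summed.  GTF coordinates are
    1-based inclusive, so the length of ``[a, b]`` is ``b - a + 1``.
    Genes with no exon features are absent from the result.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise FormatError(f"{gtf_path}:{lineno}: expected 9 tab-separated fields")
            if parts[2] != "exon":
                continue
            start, end = int(parts[3]), int(parts[4])
            if end < start:
                raise FormatError(
                    f"{gtf_path}:{lineno}: exon end {end} < start {start}"
                )
            m = _GENE_ID_RE.search(parts[8])
            if m is None:
                raise FormatError(f"{gtf_path}:{lineno}: no gene_id attribute")
            exons.setdefault(m.group(1), []).append((start, end))
    return {gene: _merged_length(iv) for gene, iv in exons.items()}


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    """Total covered bases of a set of 1-based inclusive intervals."""
    total = 0
    cur_start = cur_end = None
    for start, end in sorted(intervals):
        if cur_end is None:
            cur_start, cur_end = start, end
        elif start <= cur_end + 1:
            cur_end = max(cur_end, end)
        else:
            total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
    if cur_end is not None:
        total += cur_end - cur_start + 1
    return total


def classify_genes(genes: pd.DataFrame, patterns: dict | None = None) -> pd.DataFrame:
    """Fill the ``gene_class`` column from id/symbol prefix rules.

    Spike-ins are recognised from the gene id, mitochondrial and
    ribosomal-protein genes from the symbol.  Precedence is
    spikein > mito > ribo; unmatched genes are ``ordinary``.
    """
    rules = dict(DEFAULT_CLASS_PATTERNS)
    if patterns:
        rules.update(patterns)
    out = genes.copy()
    ids = out["gene_id"].astype(str)
    symbols = out["symbol"].astype(str)
    gene_class = pd.Series("ordinary", index=out.index, dtype=object)
    ribo = symbols.str.startswith(tuple(rules["ribo_symbol_prefix"]))
    gene_class[ribo] = "ribo"
    mito = symbols.str.startswith(tuple(rules["mito_symbol_prefix"]))
    gene_class[mito] = "mito"
    spike = ids.str.startswith(tuple(rules["spikein_id_prefix"]))
    gene_class[spike] = "spikein"
    out["gene_class"] = gene_class
    return out
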