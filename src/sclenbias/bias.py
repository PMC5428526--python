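"""Gene-length bias machinery: normalisation, per-gene summaries, length
binning and trend statistics.

Full-length library preparation fragments cDNA, so for the same number of
transcripts a long gene yields more fragments and therefore higher counts —
and a lower chance of dropping out entirely.  UMI protocols count molecules,
not fragments, so their expected counts do not depend on gene length, and
dividing UMI counts by gene length (RPKM) *introduces* a length trend
instead of removing one.

Per-gene summaries computed here:

* ``mean_log_cpm`` — mean over cells of log2(CPM + pseudocount), CPM being
  counts scaled to a library size of one million.
* ``dropout_rate`` — share of cells in which the gene's count is zero.
* ``mean_log_rpkm`` — as above after additionally dividing by gene length
  in kilobases.

Genes are then placed in equal-occupancy length bins (shortest genes in
bin 1) and each bin is summarised by the median and quartiles of the three
statistics.  The visual trend across bins is quantified by Spearman rank
correlations of gene length against each statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .ingest import ExpressionDataset


def library_sizes(dataset: ExpressionDataset, exclude_spikeins: bool = True) -> np.ndarray:
    """Per-cell total counts; spike-in rows excluded by default.

    Spike-in content varies strongly between protocols, so depth
    normalisation over endogenous genes only is the default.
    """
    counts = dataset.counts
    if exclude_spikeins:
        keep = (dataset.genes["gene_class"] != "spikein").to_numpy()
        counts = counts[keep, :]
    return counts.sum(axis=0)


def log_cpm(counts, lib_sizes=None, pseudocount: float = 1.0,
            scale: float = 1e6) -> np.ndarray:
    """log2(counts-per-million + pseudocount), per entry.

    ``lib_sizes`` defaults to the column sums of the supplied (post-filter)
    matrix.  A zero library size is an error naming the cell column.
    """
    counts = np.asarray(counts, dtype=float)
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    zero = np.flatnonzero(lib_sizes == 0)
    if zero.size:
        raise ValueError(f"zero library size in cell column(s) {zero.tolist()}")
    return np.log2(counts / lib_sizes * scale + pseudocount)


def rpkm(counts, lengths_bp, lib_sizes=None, scale: float = 1e6) -> np.ndarray:
    """Reads per kilobase per million: count / (library/1e6) / (length/1000)."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths_bp, dtype=float)
    if np.isnan(lengths).any():
        bad = np.flatnonzero(np.isnan(lengths))
        raise ValueError(f"missing gene length for row(s) {bad.tolist()}")
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    zero = np.flatnonzero(lib_sizes == 0)
    if zero.size:
        raise ValueError(f"zero library size in cell column(s) {zero.tolist()}")
    return counts / (lib_sizes / scale) / (lengths[:, None] / 1000.0)


def log_rpkm(counts, lengths_bp, lib_sizes=None, pseudocount: float = 1.0) -> np.ndarray:
    return np.log2(rpkm(counts, lengths_bp, lib_sizes=lib_sizes) + pseudocount)


def assign_length_bins(lengths_bp, gene_ids=None, n_bins: int = 10) -> np.ndarray:
    """Equal-occupancy length bins; bin 1 holds the shortest genes.

    Genes are sorted by (length, gene_id) and cut into ``n_bins`` contiguous
    groups whose sizes differ by at most one; when the division is uneven the
    last bins take the extra gene each.  The gene-id tiebreak makes the
    assignment deterministic under duplicated lengths.
    """
    lengths = np.asarray(lengths_bp, dtype=float)
    n = lengths.size
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds number of genes ({n})")
    if gene_ids is None:
        gene_ids = np.arange(n)
    gene_ids = np.asarray(gene_ids)
    order = np.lexsort((gene_ids, lengths))
    base, extra = divmod(n, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    if extra:
        sizes[-extra:] += 1
    bin_of_rank = np.repeat(np.arange(1, n_bins + 1), sizes)
    bins = np.empty(n, dtype=int)
    bins[order] = bin_of_rank
    return bins


def gene_summaries(dataset: ExpressionDataset, pseudocount: float = 1.0,
                   n_bins: int = 10, exclude_spikeins: bool = True,
                   log_of_mean: bool = False) -> pd.DataFrame:
    """Per-gene expression/dropout summary table with length-bin assignment.

    By default the per-gene count statistic is the mean over cells of
    log2(CPM + pseudocount).  ``log_of_mean=True`` instead logs the mean CPM
    (the two orderings of mean and log are both in circulation; the default
    averages the logs).
    """
    lib = library_sizes(dataset, exclude_spikeins=exclude_spikeins)
    counts = dataset.counts
    lengths = dataset.genes["length_bp"].to_numpy(dtype=float)
    if log_of_mean:
        cpm = counts / lib * 1e6
        mean_log_cpm = np.log2(cpm.mean(axis=1) + pseudocount)
        mean_log_rpkm = np.log2(
            (cpm / (lengths[:, None] / 1000.0)).mean(axis=1) + pseudocount
        )
    else:
        mean_log_cpm = log_cpm(counts, lib_sizes=lib, pseudocount=pseudocount).mean(axis=1)
        mean_log_rpkm = log_rpkm(counts, lengths, lib_sizes=lib,
                                 pseudocount=pseudocount).mean(axis=1)
    out = pd.DataFrame(
        {
            "gene_id": dataset.genes["gene_id"].to_numpy(),
            "length_bp": lengths,
            "mean_log_cpm": mean_log_cpm,
            "dropout_rate": (counts == 0).sum(axis=1) / dataset.n_cells,
            "mean_log_rpkm": mean_log_rpkm,
        }
    )
    out["bin_id"] = assign_length_bins(lengths, out["gene_id"].to_numpy(), n_bins=n_bins)
    return out


def bin_summaries(summaries: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of each per-gene statistic, per length bin.

    Quartiles use linear interpolation. One row per bin, ordered bin 1..n.
    """
    rows = []
    for bin_id, grp in summaries.groupby("bin_id", sort=True):
        row = {
            "bin_id": bin_id,
            "n_genes": len(grp),
            "length_min": grp["length_bp"].min(),
            "length_max": grp["length_bp"].max(),
        }
        for stat in ("mean_log_cpm", "dropout_rate", "mean_log_rpkm"):
            q1, med, q3 = np.percentile(grp[stat], [25, 50, 75])
            row[f"{stat}_q1"] = q1
            row[f"{stat}_median"] = med
            row[f"{stat}_q3"] = q3
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BiasStatistics:
    """Spearman correlations of gene length against the per-gene statistics.

    A positive ``rho_count`` with a negative ``rho_dropout`` is the
    full-length fragmentation signature; both near zero is the UMI
    signature.  ``rho_rpkm`` turning negative on UMI data is the distortion
    introduced by dividing molecule counts by gene length.
    Undefined correlations (constant input) are NaN.
    """

    rho_count: float
    rho_dropout: float
    rho_rpkm: float
    p_count: float
    p_dropout: float
    p_rpkm: float

    def to_dict(self) -> dict[str, float]:
        return {
            "rho_count": self.rho_count,
            "rho_dropout": self.rho_dropout,
            "rho_rpkm": self.rho_rpkm,
            "p_count": self.p_count,
            "p_dropout": self.p_dropout,
            "p_rpkm": self.p_rpkm,
        }


def _spearman(x, y) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan"), float("nan")
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


def length_bias_statistics(summaries: pd.DataFrame) -> BiasStatistics:
    """Rank-correlate gene length with count level, dropout, and RPKM level.

    Ties are midranked; p-values use the large-sample t approximation.
    Requires at least 10 genes.
    """
    if len(summaries) < 10:
        raise ValueError("need at least 10 genes for trend statistics")
    lengths = summaries["length_bp"]
    rho_c, p_c = _spearman(lengths, summaries["mean_log_cpm"])
    rho_d, p_d = _spearman(lengths, summaries["dropout_rate"])
    rho_r, p_r = _spearman(lengths, summaries["mean_log_rpkm"])
    return BiasStatistics(rho_c, rho_d, rho_r, p_c, p_d, p_r)


def plot_bin_summaries(summaries: pd.DataFrame, out_path=None, title: str = ""):
    """Three-panel per-bin boxplot figure (count level, dropout, RPKM level).

    Returns the matplotlib figure; saves to ``out_path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [
        ("mean_log_cpm", "average log2 CPM"),
        ("dropout_rate", "dropout rate per gene"),
        ("mean_log_rpkm", "average log2 RPKM"),
    ]
    fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharex=True)
    bins = sorted(summaries["bin_id"].unique())
    for ax, (stat, label) in zip(axes, panels):
        data = [summaries.loc[summaries["bin_id"] == b, stat] for b in bins]
        ax.boxplot(data, tick_labels=[str(b) for b in bins], showfliers=False)
        ax.set_xlabel("gene length bin (short → long)")
        ax.set_ylabel(label)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig
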