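"""Two-group differential expression stand-in.

This stage exists so that "what fraction of the uniquely detected genes is
differentially expressed between conditions" can be asked end to end.  It
keeps the design of a count-based DE analysis — size-factor normalisation
to absorb depth and composition differences, a per-gene two-sample test,
BH correction, and a log-fold-change cut-off — while deliberately staying
simple: median-of-ratios size factors and a rank-sum test on normalised
log expression, with the fold-change threshold applied after testing.
It makes no negative-binomial dispersion assumptions and is not a
re-implementation of any published GLM-based DE method.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from .ingest import ExpressionDataset
from .stats import benjamini_hochberg

logger = logging.getLogger(__name__)


def median_ratio_size_factors(counts) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference profile is the per-gene geometric mean over cells,
    computed on genes expressed in every cell; each cell's factor is the
    median of its counts over the reference profile.  When no gene is
    expressed in all cells the factors fall back to library sizes (with a
    logged warning), so depth is still corrected even if composition
    cannot be.
    """
    counts = np.asarray(counts, dtype=float)
    all_expressed = (counts > 0).all(axis=1)
    if not all_expressed.any():
        logger.warning(
            "no gene expressed in every cell; falling back to library-size factors"
        )
        factors = counts.sum(axis=0).astype(float)
        if (factors == 0).any():
            raise ValueError("cannot compute size factors with all-zero cells")
    else:
        ref = counts[all_expressed, :]
        log_geomean = np.log(ref).mean(axis=1)
        ratios = np.log(ref) - log_geomean[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    return factors / np.exp(np.log(factors).mean())


def normalized_log_expression(counts, size_factors=None,
                              pseudocount: float = 1.0) -> np.ndarray:
    """log2 of size-factor-normalised CPM plus pseudocount.

    Effective library size of cell c is ``size_factor_c * G`` where G is
    the geometric mean of the raw library sizes, so that library-size
    factors reproduce plain CPM exactly.
    """
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero cell column; filter cells first")
    if size_factors is None:
        size_factors = median_ratio_size_factors(counts)
    geo_lib = np.exp(np.log(lib).mean())
    norm_cpm = counts / (size_factors * geo_lib) * 1e6
    return np.log2(norm_cpm + pseudocount)


def de_two_group(dataset: ExpressionDataset, group_labels,
                 lfc_cutoff: float = 0.0, alpha: float = 0.05,
                 reference: str | None = None,
                 pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene two-group comparison on normalised log expression.

    ``group_labels`` is a length-``n_cells`` vector with exactly two levels;
    ``reference`` names the baseline level (default: first level in sorted
    order).  The log2 fold change is mean(other) - mean(reference); the
    p-value is a rank-sum test per gene, BH-adjusted across genes.  A gene
    is called significant when ``fdr <= alpha`` and
    ``|log2_fold_change| >= lfc_cutoff``.
    """
    labels = np.asarray(group_labels)
    if labels.size != dataset.n_cells:
        raise ValueError("group_labels length must match number of cells")
    levels = sorted(set(labels.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not among levels {levels}")
    other = levels[1] if reference == levels[0] else levels[0]
    mask_ref = labels == reference
    mask_other = labels == other
    if mask_ref.sum() < 2 or mask_other.sum() < 2:
        raise ValueError("each group needs at least 2 cells")

    expr = normalized_log_expression(dataset.counts, pseudocount=pseudocount)
    lfc = expr[:, mask_other].mean(axis=1) - expr[:, mask_ref].mean(axis=1)
    res = scipy.stats.mannwhitneyu(
        expr[:, mask_other], expr[:, mask_ref], axis=1,
        alternative="two-sided", method="asymptotic",
    )
    p = np.asarray(res.pvalue, dtype=float)
    p[np.isnan(p)] = 1.0  # constant genes carry no evidence
    fdr = benjamini_hochberg(p)
    return pd.DataFrame(
        {
            "gene_id": dataset.genes["gene_id"].to_numpy(),
            "log2_fold_change": lfc,
            "p_value": p,
            "fdr": fdr,
            "significant": (fdr <= alpha) & (np.abs(lfc) >= lfc_cutoff),
        }
    )


def de_fraction_in_set(de: pd.DataFrame, gene_set: set) -> dict[str, float]:
    """Fraction of a gene set called significant, next to the overall rate.

    Returns ``set_fraction`` (significant within the set / set size),
    ``overall_fraction`` (significant / tested), plus the raw counts.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    tested = set(de["gene_id"])
    if not gene_set <= tested:
        missing = sorted(gene_set - tested)
        raise ValueError(f"gene set members not in DE table: {missing[:5]}")
    sig = set(de.loc[de["significant"], "gene_id"])
    return {
        "set_significant": len(sig & gene_set),
        "set_size": len(gene_set),
        "set_fraction": len(sig & gene_set) / len(gene_set),
        "overall_significant": len(sig),
        "overall_tested": len(de),
        "overall_fraction": len(sig) / len(de),
    }
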