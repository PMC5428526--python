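"""Statistics for comparing detection regions: rank-sum test on gene
lengths, hypergeometric gene-set enrichment, and the variance-ratio test on
category median lengths.

Gene-set categories are supplied in GMT format (one category per line:
id, description, member ids, tab-separated), keeping the module free of any
annotation-database dependency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

_ALTERNATIVES = {"two_sided": "two-sided", "less": "less", "greater": "greater"}


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided") -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test of two independent samples.

    Returns ``(W, p)`` where W is the rank sum of *x* in the pooled
    midranked sample.  The p-value is exact (full enumeration of rank
    assignments) when the pooled sample has at most 16 untied observations;
    otherwise the normal approximation with tie and continuity corrections
    is used.  ``alternative='less'`` tests whether *x* is stochastically
    smaller than *y*.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 16 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative=_ALTERNATIVES[alternative], method=method,
        use_continuity=True,
    )
    ranks = scipy.stats.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    return w, float(res.pvalue)


def hypergeometric_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    Of a universe of ``N`` genes, ``K`` belong to the category and ``n``
    were drawn (the gene set of interest); ``k`` is the observed overlap.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if K > N or n > N or K < 0 or n < 0:
        raise ValueError(f"inconsistent arguments K={K}, n={n}, N={N}")
    return float(scipy.stats.hypergeom.sf(k - 1, N, K, n))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class GeneSetCategory:
    """A named gene set (e.g. a GO category) read from a GMT line."""

    category_id: str
    name: str
    member_gene_ids: frozenset

    def __post_init__(self):
        object.__setattr__(self, "member_gene_ids", frozenset(self.member_gene_ids))


def read_gmt(path) -> list[GeneSetCategory]:
    """Read gene-set categories from a GMT file (id, name, members...)."""
    categories = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs id, name, members")
            members = [m for m in parts[2:] if m]
            categories.append(GeneSetCategory(parts[0], parts[1], frozenset(members)))
    return categories


def write_gmt(categories: list[GeneSetCategory], path) -> None:
    with open(path, "w") as fh:
        for cat in categories:
            fh.write("\t".join([cat.category_id, cat.name,
                                *sorted(cat.member_gene_ids)]) + "\n")


def enrich(gene_set: set, categories: list[GeneSetCategory], universe: set,
           lengths: dict | None = None, fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of each category in *gene_set*.

    Categories are intersected with the universe before testing; categories
    with no universe member are skipped.  P-values are BH-adjusted across
    the tested categories and significance called at ``fdr <= fdr_alpha``.
    When a gene_id -> length_bp mapping is supplied, each category receives
    the median length of its universe members with known lengths.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    N, n = len(universe), len(gene_set)
    rows = []
    for cat in categories:
        members = cat.member_gene_ids & universe
        if not members:
            continue
        K = len(members)
        k = len(members & gene_set)
        p = hypergeometric_test(k, K, n, N)
        median_len = np.nan
        if lengths is not None:
            known = [lengths[g] for g in members
                     if g in lengths and not pd.isna(lengths[g])]
            if known:
                median_len = float(np.median(known))
        rows.append((cat.category_id, cat.name, K, k, p, median_len))
    out = pd.DataFrame(
        rows,
        columns=["category_id", "name", "n_category_in_universe", "n_overlap",
                 "p_value", "median_member_length"],
    )
    out["fdr"] = benjamini_hochberg(out["p_value"]) if len(out) else []
    out["significant"] = out["fdr"] <= fdr_alpha
    return out


def category_length_spread_test(lengths_a, lengths_b,
                                log_scale: bool = False) -> tuple[float, float]:
    """Variance-ratio (F) test of spread of two sets of category median lengths.

    Returns ``(F, p)`` with ``F = var(a)/var(b)`` (sample variances) and a
    two-sided p-value ``2 * min(P[F_{dfa,dfb} >= F], P[<= F])``.
    ``log_scale=True`` compares variances of the logged lengths instead —
    the scale on which a fold-difference in spread reads the same at all
    lengths.
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if log_scale:
        a, b = np.log(a), np.log(b)
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    if var_b == 0:
        raise ValueError("zero variance in denominator sample")
    F = var_a / var_b
    dfa, dfb = a.size - 1, b.size - 1
    p = 2 * min(scipy.stats.f.sf(F, dfa, dfb), scipy.stats.f.cdf(F, dfa, dfb))
    return float(F), float(min(p, 1.0))
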