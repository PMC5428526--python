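import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sclenbias.bias import (
    assign_length_bins,
    bin_summaries,
    gene_summaries,
    length_bias_statistics,
    log_cpm,
    log_rpkm,
    rpkm,
)
from sclenbias.bias import _spearman
from .conftest import make_dataset


class TestLogCpm:
    def test_pseudocount_floor_and_closed_form(self):
        counts = np.array([[0], [1]])
        out = log_cpm(counts)  # library size 1
        assert out[0, 0] == 0.0
        assert out[1, 0] == pytest.approx(math.log2(1e6 + 1))

    def test_scale_invariance_per_cell(self, rng):
        counts = rng.integers(0, 50, size=(30, 4))
        counts[0] += 1  # no zero columns
        doubled = counts.copy()
        doubled[:, 2] *= 7
        np.testing.assert_allclose(log_cpm(counts), log_cpm(doubled))

    def test_zero_library_names_cell(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            log_cpm(np.array([[1, 0], [2, 0]]))


class TestRpkm:
    def test_unit_case_and_short_gene_inflation(self):
        counts = np.array([[10], [10]])
        lib = np.array([1e6])
        out = rpkm(counts, [1000.0, 500.0], lib_sizes=lib)
        assert out[0, 0] == pytest.approx(10.0)
        assert out[1, 0] == pytest.approx(20.0)  # shorter gene inflated 2x

    def test_equals_cpm_at_length_1000_every_entry(self, rng):
        counts = rng.integers(0, 100, size=(20, 5))
        counts[0] += 1
        lengths = np.full(20, 1000.0)
        cpm = counts / counts.sum(axis=0) * 1e6
        np.testing.assert_allclose(rpkm(counts, lengths), cpm)

    def test_missing_length_errors(self):
        with pytest.raises(ValueError, match="missing"):
            rpkm(np.array([[1], [2]]), [1000.0, np.nan])


class TestGeneSummaries:
    def test_dropout_rates(self):
        ds = make_dataset(np.array([[0, 0, 3, 0]] * 10 + [[1, 2, 3, 4]] * 10))
        gs = gene_summaries(ds)
        assert gs["dropout_rate"].iloc[0] == 0.75
        assert gs["dropout_rate"].iloc[10] == 0.0

    def test_hand_computed_two_gene_toy(self):
        ds = make_dataset(np.array([[1, 0], [9, 10]]), lengths=[1000.0, 2000.0],
                          gene_ids=["a", "b"])
        gs = gene_summaries(ds, n_bins=2).set_index("gene_id")
        # libraries are 10 and 10; CPM of count 1 is 1e5
        expect_a = (math.log2(1e5 + 1) + math.log2(0 + 1)) / 2
        expect_b = (math.log2(9e5 + 1) + math.log2(1e6 + 1)) / 2
        assert gs.loc["a", "mean_log_cpm"] == pytest.approx(expect_a)
        assert gs.loc["b", "mean_log_cpm"] == pytest.approx(expect_b)
        # RPKM for gene b (2 kb): divide CPM by 2
        expect_b_rpkm = (math.log2(4.5e5 + 1) + math.log2(5e5 + 1)) / 2
        assert gs.loc["b", "mean_log_rpkm"] == pytest.approx(expect_b_rpkm)
        assert list(gs["bin_id"]) == [1, 2]

    def test_spikeins_excluded_from_library_size(self):
        counts = np.array([[5, 5], [95, 5]])
        ds = make_dataset(counts, classes=["ordinary", "spikein"])
        gs = gene_summaries(ds, n_bins=1)
        # endogenous library = 5 per cell, so gene 1 sits at 1e6 CPM in both
        assert gs["mean_log_cpm"].iloc[0] == pytest.approx(math.log2(1e6 + 1))


class TestLengthBins:
    def test_even_split(self):
        bins = assign_length_bins(np.arange(20) * 10.0, n_bins=10)
        sizes = np.bincount(bins)[1:]
        assert (sizes == 2).all()

    def test_remainder_goes_to_last_bins(self):
        lengths = np.arange(1003, dtype=float)
        bins = assign_length_bins(lengths, n_bins=10)
        sizes = np.bincount(bins)[1:]
        assert sizes.tolist() == [100] * 7 + [101] * 3
        # bin 1 holds the shortest genes
        assert set(bins[:100]) == {1}

    def test_tie_break_is_deterministic(self):
        lengths = np.full(30, 1234.0)
        ids = np.array([f"g{i:02d}" for i in range(30)])
        first = assign_length_bins(lengths, ids, n_bins=4)
        second = assign_length_bins(lengths, ids, n_bins=4)
        assert np.array_equal(first, second)
        # lexicographically smallest ids land in bin 1
        assert set(ids[first == 1]) == set(sorted(ids)[:7])

    @pytest.mark.parametrize("n_genes", [20, 1003, 9962])
    def test_sizes_and_ordered_concatenation(self, rng, n_genes):
        lengths = rng.lognormal(8, 1, size=n_genes)
        ids = np.array([f"g{i:05d}" for i in range(n_genes)])
        bins = assign_length_bins(lengths, ids, n_bins=10)
        sizes = np.bincount(bins)[1:]
        assert sizes.max() - sizes.min() <= 1
        sorted_ids = list(ids[np.lexsort((ids, lengths))])
        concat = []
        for b in range(1, 11):
            members = np.flatnonzero(bins == b)
            members = members[np.lexsort((ids[members], lengths[members]))]
            concat.extend(ids[members])
        assert concat == sorted_ids

    def test_invalid_bin_counts(self):
        with pytest.raises(ValueError):
            assign_length_bins([1.0, 2.0], n_bins=0)
        with pytest.raises(ValueError):
            assign_length_bins([1.0, 2.0], n_bins=3)


class TestBinSummaries:
    def test_median_and_iqr(self):
        df = pd.DataFrame(
            {
                "bin_id": [1, 1, 1, 2, 2, 2],
                "length_bp": [1, 2, 3, 4, 5, 6.0],
                "mean_log_cpm": [1.0, 2.0, 3.0, 7.0, 7.0, 7.0],
                "dropout_rate": [0.1, 0.2, 0.3, 0.0, 0.0, 0.0],
                "mean_log_rpkm": [1.0, 2.0, 3.0, 5.0, 5.0, 5.0],
            }
        )
        bs = bin_summaries(df).set_index("bin_id")
        assert bs.loc[1, "mean_log_cpm_median"] == 2.0
        assert bs.loc[2, "mean_log_cpm_q3"] - bs.loc[2, "mean_log_cpm_q1"] == 0.0
        assert bs["n_genes"].sum() == 6


class TestSpearmanTrends:
    def test_monotone_and_antimonotone(self, rng):
        lengths = np.sort(rng.lognormal(8, 1, size=50))
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(50)],
                "length_bp": lengths,
                "mean_log_cpm": np.log2(lengths),      # monotone increasing
                "dropout_rate": 1 / (1 + lengths),     # monotone decreasing
                "mean_log_rpkm": np.linspace(0, 1, 50),
            }
        )
        stats = length_bias_statistics(df)
        assert stats.rho_count == pytest.approx(1.0)
        assert stats.rho_dropout == pytest.approx(-1.0)

    def test_null_permutation_is_near_zero(self, rng):
        n = 5000
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "length_bp": rng.lognormal(8, 1, size=n),
                "mean_log_cpm": rng.normal(size=n),
                "dropout_rate": rng.uniform(size=n),
                "mean_log_rpkm": rng.normal(size=n),
            }
        )
        stats = length_bias_statistics(df)
        assert abs(stats.rho_count) < 0.1
        assert abs(stats.rho_dropout) < 0.1

    def test_constant_statistic_reported_missing(self):
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(12)],
                "length_bp": np.arange(12, dtype=float) + 100,
                "mean_log_cpm": 1.0,
                "dropout_rate": np.linspace(0, 1, 12),
                "mean_log_rpkm": np.linspace(0, 1, 12),
            }
        )
        stats = length_bias_statistics(df)
        assert math.isnan(stats.rho_count)
        assert not math.isnan(stats.rho_dropout)

    def test_requires_ten_genes(self):
        df = pd.DataFrame(
            {"gene_id": ["a"], "length_bp": [1.0], "mean_log_cpm": [1.0],
             "dropout_rate": [0.0], "mean_log_rpkm": [1.0]}
        )
        with pytest.raises(ValueError):
            length_bias_statistics(df)

    def test_matches_exact_rank_formula_on_all_permutations(self):
        # brute-force oracle: rho = 1 - 6*sum(d^2)/(n(n^2-1)) on tie-free ranks
        x = np.arange(1.0, 7.0)
        for perm in itertools.permutations(range(6)):
            y = np.array(perm, dtype=float)
            rho, _ = _spearman(x, y)
            d = x - 1 - y
            expected = 1 - 6 * (d**2).sum() / (6 * 35)
            assert rho == pytest.approx(expected, abs=1e-12)
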