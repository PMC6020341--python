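"""Time-series filters, island-size sign test, response labels, noise contrast."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from cginoise import response_enrichment as re_
from cginoise import synthetic_data as syn


class TestFilterTimeseries:
    def test_cage_75_percent_boundary_removed(self):
        counts = pd.DataFrame({f"s{i}": [1 if i < 3 else 0, 1] for i in range(4)},
                              index=["boundary", "always"])
        kept = re_.filter_timeseries(counts, kind="cage")
        assert list(kept.index) == ["always"]   # detected in exactly 75% -> out

    def test_rnaseq_mean_five_boundary_removed(self):
        counts = pd.DataFrame({"s1": [5, 6], "s2": [5, 6]},
                              index=["at5", "above"])
        kept = re_.filter_timeseries(counts, kind="rnaseq")
        assert list(kept.index) == ["above"]    # mean exactly 5 -> out

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            re_.filter_timeseries(pd.DataFrame({"a": [1]}), kind="cagee")


class TestAssignCgiToPeaks:
    def _islands(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    def test_island_overlapping_centred_window_assigned(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "pos": [1000]}, index=["p1"])
        sizes = re_.assign_cgi_to_peaks(
            peaks, self._islands([("chr1", 1200, 1500, "i")]))
        # window [750, 1250) overlaps [1200, 1500) by 50 bp
        assert sizes["p1"] == 300

    def test_island_outside_window_unassigned(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "pos": [1000]}, index=["p1"])
        sizes = re_.assign_cgi_to_peaks(
            peaks, self._islands([("chr1", 1300, 1500, "i")]))
        assert sizes["p1"] == 0

    def test_tie_goes_to_longer_island(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "pos": [1000]}, index=["p1"])
        islands = self._islands([("chr1", 700, 800, "short"),
                                 ("chr1", 1150, 1650, "long")])
        # overlaps: short 50 bp ([750,800)), long 100 ([1150,1250)) -> long
        sizes = re_.assign_cgi_to_peaks(peaks, islands)
        assert sizes["p1"] == 500


class TestNaiveLog2fc:
    def test_fourfold_increase_without_pseudocount(self):
        counts = pd.DataFrame({"t0": [10], "t1": [40]}, index=["g"])
        fc = re_.naive_log2fc(counts, [["t0"], ["t1"]], pseudocount=0)
        assert fc.loc["g", "fc_0v1"] == pytest.approx(2.0)

    def test_equal_means_give_zero(self):
        counts = pd.DataFrame({"t0a": [8], "t0b": [12], "t1": [10]},
                              index=["g"])
        fc = re_.naive_log2fc(counts, [["t0a", "t0b"], ["t1"]])
        assert fc.loc["g", "fc_0v1"] == 0

    def test_zero_counts_with_pseudocount(self):
        counts = pd.DataFrame({"t0": [0], "t1": [0]}, index=["g"])
        fc = re_.naive_log2fc(counts, [["t0"], ["t1"]], pseudocount=1)
        assert fc.loc["g", "fc_0v1"] == 0

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"t0": [-1], "t1": [2]}, index=["g"])
        with pytest.raises(ValueError):
            re_.naive_log2fc(counts, [["t0"], ["t1"]])


def sign_test_oracle(early_sizes, late_sizes):
    """Independent paired-sample sign test: count strict wins, exact
    binomial upper tail by direct summation of the probability mass."""
    wins = ties = 0
    for e, l in zip(early_sizes, late_sizes):
        if e < l:
            wins += 1
        elif e == l:
            ties += 1
    n = len(early_sizes) - ties
    from math import comb
    p = sum(comb(n, k) for k in range(wins, n + 1)) / 2 ** n
    return n, wins, p


class TestCgiSizeEnrichment:
    def _inputs(self, seed, n=400, top_n=100):
        rng = np.random.default_rng(seed)
        idx = [f"g{i}" for i in range(n)]
        sizes = pd.Series(rng.integers(200, 5000, n).astype(float), index=idx)
        ts = pd.DataFrame({"fc_0v1": rng.normal(0, 1, n),
                           "fc_1v2": rng.normal(0, 1, n)}, index=idx)
        return ts, sizes

    def test_matches_independent_sign_test_on_random_instances(self):
        for seed in range(50):
            ts, sizes = self._inputs(seed)
            res = re_.cgi_size_enrichment(ts, sizes, "fc_0v1", "fc_1v2",
                                          top_n=100)
            early = [g for g in sorted(ts.index,
                                       key=lambda g: (-ts.loc[g, "fc_0v1"], g))][:100]
            late = [g for g in sorted(ts.index,
                                      key=lambda g: (-ts.loc[g, "fc_1v2"], g))][:100]
            n, wins, p = sign_test_oracle(sizes[early].tolist(),
                                          sizes[late].tolist())
            assert res.n_pairs == n
            assert res.n_early_smaller == wins
            assert res.p_one_tailed == pytest.approx(p, rel=1e-12)

    def test_all_smaller_closed_form(self):
        idx = [f"g{i}" for i in range(16)]
        sizes = pd.Series([100] * 8 + [1000] * 8, index=idx, dtype=float)
        ts = pd.DataFrame({
            "fc_0v1": [10] * 8 + [0] * 8,    # early top = small islands
            "fc_1v2": [0] * 8 + [10] * 8,    # late top = large islands
        }, index=idx)
        res = re_.cgi_size_enrichment(ts, sizes, "fc_0v1", "fc_1v2", top_n=8)
        assert res.n_early_smaller == 8
        assert res.p_one_tailed == pytest.approx(0.5 ** 8)
        assert res.direction == "short_early"

    def test_reversing_comparisons_flips_direction_and_successes(self):
        ts, sizes = self._inputs(7)
        a = re_.cgi_size_enrichment(ts, sizes, "fc_0v1", "fc_1v2", top_n=100)
        b = re_.cgi_size_enrichment(ts, sizes, "fc_1v2", "fc_0v1", top_n=100)
        # same genes pair up rank-for-rank; strict wins swap sides
        assert a.n_pairs == b.n_pairs
        assert b.n_early_smaller == a.n_pairs - a.n_early_smaller

    def test_identical_ranked_lists_all_tied_rejected(self):
        idx = [f"g{i}" for i in range(20)]
        sizes = pd.Series(500.0, index=idx)
        ts = pd.DataFrame({"fc_0v1": np.arange(20.0),
                           "fc_1v2": np.arange(20.0)}, index=idx)
        with pytest.raises(ValueError, match="tied"):
            re_.cgi_size_enrichment(ts, sizes, "fc_0v1", "fc_1v2", top_n=20)

    def test_genes_without_island_excluded_before_ranking(self):
        ts, sizes = self._inputs(9)
        sizes.iloc[:200] = 0
        res = re_.cgi_size_enrichment(ts, sizes, "fc_0v1", "fc_1v2", top_n=150)
        assert res.n_pairs + res.ties_excluded == 150

    def test_top_n_capped_with_warning(self):
        ts, sizes = self._inputs(11, n=50)
        res = re_.cgi_size_enrichment(ts, sizes, "fc_0v1", "fc_1v2", top_n=500)
        assert res.n_pairs + res.ties_excluded == 50

    def test_uses_exact_binomial_tail(self):
        ts, sizes = self._inputs(13)
        res = re_.cgi_size_enrichment(ts, sizes, "fc_0v1", "fc_1v2", top_n=100)
        assert res.p_one_tailed == pytest.approx(
            binom.sf(res.n_early_smaller - 1, res.n_pairs, 0.5))


class TestLabelResponse:
    def test_identical_groups_all_nochange(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(20, (100, 25)),
                              index=[f"g{i}" for i in range(100)])
        labels = re_.label_response(counts, counts.copy())
        assert (labels == "nochange").all()

    def test_planted_shift_labelled_up(self):
        cm_un, truth = syn.simulate_counts(500, 200, seed=21)
        shifted = truth.copy()
        boost = np.ones(len(truth))
        boost[:100] = 2.0
        shifted["true_mean"] = truth["true_mean"] * boost
        cm_st, _ = syn.simulate_counts(500, 200, seed=22, truth=shifted)
        labels = re_.label_response(cm_un, cm_st)
        assert (labels.iloc[:100] == "up").sum() >= 80
        assert len(labels) == 500   # labels partition the gene universe

    def test_small_groups_rejected(self):
        counts = pd.DataFrame(np.ones((10, 5)))
        with pytest.raises(ValueError, match="cells"):
            re_.label_response(counts, counts)


class TestNoiseVsResponse:
    def _noise(self, values, idx):
        return pd.DataFrame({"cv2": values, "rcv2": values}, index=idx)

    def test_binning_arithmetic(self):
        idx = ["a", "b", "c"]
        sizes = pd.Series([100.0, 600.0, 1100.0], index=idx)
        noise = self._noise([1.0, 1.0, 1.0], idx)
        labels = pd.Series("up", index=idx)
        summary, _ = re_.noise_vs_response(noise, labels, sizes,
                                           min_bin_genes=1)
        cgi = summary[summary["stratum"] == "cgi"]
        assert sorted(cgi["bin"]) == [0, 1, 2]

    def test_shifted_up_distribution_detected_one_tailed(self):
        rng = np.random.default_rng(1)
        idx = [f"g{i}" for i in range(300)]
        base = np.abs(rng.normal(1, 0.3, 300))
        vals = base + np.where(np.arange(300) < 150, 1.0, 0.0)
        noise = self._noise(vals, idx)
        labels = pd.Series(np.where(np.arange(300) < 150, "up", "nochange"),
                           index=idx)
        sizes = pd.Series(rng.integers(200, 2000, 300).astype(float),
                          index=idx)
        _, tests = re_.noise_vs_response(noise, labels, sizes)
        assert tests["cgi_up_vs_nochange"]["p"] < 0.01

    def test_sparse_bins_reported_missing(self):
        idx = ["a", "b", "c", "d"]
        sizes = pd.Series([300.0, 300.0, 300.0, 900.0], index=idx)
        noise = self._noise([1.0, 1.1, 0.9, 1.0], idx)
        labels = pd.Series(["up", "up", "up", "up"], index=idx)
        summary, _ = re_.noise_vs_response(noise, labels, sizes)
        cgi = summary[summary["stratum"] == "cgi"].set_index("bin")
        assert not np.isnan(cgi.loc[0, "mean_noise"])
        assert np.isnan(cgi.loc[1, "mean_noise"])
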