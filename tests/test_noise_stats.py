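"""Filters, size factors, moments and the mean-CV2 gamma fit."""

import numpy as np
import pandas as pd
import pytest

from cginoise import noise_stats as ns
from cginoise import synthetic_data as syn


def cm(arr, genes=None, cells=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cells = cells or [f"c{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=cells)


class TestFilters:
    def test_cell_filter_is_strictly_below(self):
        counts = cm(np.array([[99999, 100000]]))
        kept = ns.filter_cells(counts, min_total=100000)
        assert list(kept.columns) == ["c1"]

    def test_cell_filter_zero_threshold_is_identity(self):
        counts = cm(np.arange(12).reshape(3, 4))
        assert ns.filter_cells(counts, min_total=0).shape == (3, 4)

    def test_bad_cell_list_removed(self):
        counts = cm(np.ones((2, 5), dtype=int) * 10)
        kept = ns.filter_cells(counts, min_total=0, bad_cells=["c1", "c3"])
        assert list(kept.columns) == ["c0", "c2", "c4"]

    def test_all_cells_removed_rejected(self):
        with pytest.raises(ValueError):
            ns.filter_cells(cm([[1, 1]]), min_total=10**9)

    def test_gene_filter_boundary_is_inclusive(self):
        # detected in exactly 1% of cells -> kept (removed only if < 1%)
        counts = cm(np.zeros((2, 100), dtype=int))
        counts.iloc[0, 0] = 5
        counts.iloc[1, :] = 1
        kept = ns.filter_genes(counts, min_cell_fraction=0.01)
        assert set(kept.index) == {"g0", "g1"}

    def test_all_zero_gene_removed(self):
        counts = cm([[0, 0, 0], [1, 2, 3]])
        kept = ns.filter_genes(counts, min_cell_fraction=0.01)
        assert list(kept.index) == ["g1"]

    def test_gene_filter_zero_threshold_is_identity(self):
        counts = cm([[0, 0, 0], [1, 2, 3]])
        assert ns.filter_genes(counts, min_cell_fraction=0).shape == (2, 3)


class TestSizeFactors:
    def test_identical_cells_give_unit_factors(self):
        counts = cm(np.tile([[5], [9], [2]], (1, 30)))
        sf = ns.size_factors(counts)
        assert np.allclose(sf, 1.0)

    def test_scaled_profiles_recovered_within_two_percent(self):
        rng = np.random.default_rng(0)
        # counts large enough that integer rounding stays below the tolerance
        base = rng.integers(50, 500, 400).astype(float)
        t = np.exp(rng.normal(0, 0.3, 60))
        t /= np.exp(np.log(t).mean())
        counts = cm(np.round(base[:, None] * t[None, :]).astype(int))
        for method in ("deconvolution", "library"):
            sf = ns.size_factors(counts, method=method)
            assert np.allclose(sf.to_numpy(), t, rtol=0.02)

    def test_library_method_proportional_to_totals(self):
        rng = np.random.default_rng(1)
        counts = cm(rng.integers(0, 50, (30, 25)))
        sf = ns.size_factors(counts, method="library")
        totals = counts.sum(axis=0).to_numpy(dtype=float)
        assert np.allclose(sf / sf.iloc[0], totals / totals[0])
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)

    def test_geometric_mean_one(self, null_counts):
        counts, _ = null_counts
        sf = ns.size_factors(counts.iloc[:, :60])
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_planted_scaling_recovered_on_nb_counts(self, null_counts):
        counts, truth = null_counts
        sf = ns.size_factors(counts)
        s_true = truth.attrs["cell_scaling"].to_numpy()
        ratio = sf.to_numpy() / s_true
        ratio /= np.exp(np.log(ratio).mean())
        assert np.median(np.abs(ratio - 1)) < 0.05

    def test_zero_count_cell_rejected(self):
        counts = cm([[0, 5], [0, 5]])
        with pytest.raises(ValueError, match="zero-count"):
            ns.size_factors(counts)

    def test_few_cells_fall_back_to_library(self):
        counts = cm(np.ones((5, 10), dtype=int))
        sf = ns.size_factors(counts, method="deconvolution")
        assert np.allclose(sf, 1.0)


class TestGeneMoments:
    def test_brute_force_oracle_small_matrix(self):
        # independent recomputation of mu, var, cv2 from first principles
        rng = np.random.default_rng(5)
        counts = cm(rng.integers(0, 40, (10, 10)) + 1)
        sf = pd.Series(np.exp(rng.normal(0, 0.2, 10)), index=counts.columns)
        sf /= np.exp(np.log(sf).mean())
        table = ns.gene_moments(counts, sf)
        for g in counts.index:
            norm = [counts.loc[g, c] / sf[c] for c in counts.columns]
            mean = sum(norm) / len(norm)
            var = sum((v - mean) ** 2 for v in norm) / (len(norm) - 1)
            assert table.loc[g, "mean_norm"] == pytest.approx(mean, abs=1e-12)
            assert table.loc[g, "mu"] == pytest.approx(np.log2(mean), abs=1e-12)
            assert table.loc[g, "var_hat"] == pytest.approx(var, abs=1e-12)
            assert table.loc[g, "cv2"] == pytest.approx(var / mean**2, abs=1e-12)

    def test_mu_is_log2_of_mean(self):
        counts = cm([[1, 3, 1, 3]])
        table = ns.gene_moments(counts, pd.Series(1.0, index=counts.columns))
        assert table.loc["g0", "mu"] == pytest.approx(1.0)  # log2(2) = 1

    def test_constant_gene_has_zero_variance_and_cv2(self):
        counts = cm([[7, 7, 7, 7]])
        table = ns.gene_moments(counts, pd.Series(1.0, index=counts.columns))
        assert table.loc["g0", "var_hat"] == 0
        assert table.loc["g0", "cv2"] == 0

    def test_low_expression_genes_flagged_out_of_fit(self):
        counts = cm([[1, 1, 0, 0], [50, 60, 40, 50]])
        table = ns.gene_moments(counts, pd.Series(1.0, index=counts.columns))
        assert not table.loc["g0", "fit_ok"]   # mu below the floor
        assert table.loc["g1", "fit_ok"]

    def test_rejects_fewer_than_three_cells(self):
        with pytest.raises(ValueError):
            ns.gene_moments(cm([[1, 2]]), pd.Series(1.0, index=["c0", "c1"]))

    def test_scale_invariance_of_cv2(self, null_counts):
        counts, _ = null_counts
        sub = counts.iloc[:100, :50]
        sf = ns.size_factors(sub, method="library")
        a = ns.gene_moments(sub, sf)
        b = ns.gene_moments(sub * 3, ns.size_factors(sub * 3, method="library"))
        assert np.allclose(a["cv2"], b["cv2"])
        # mu differences between genes are preserved
        assert np.allclose(np.diff(a["mu"]), np.diff(b["mu"]))

    def test_cv2_declines_with_mean_on_nb_null(self, null_noise_table):
        table, _, _ = null_noise_table
        ok = table["fit_ok"]
        lo = table.loc[ok & (table["mu"] < table.loc[ok, "mu"].median()), "cv2"]
        hi = table.loc[ok & (table["mu"] >= table.loc[ok, "mu"].median()), "cv2"]
        assert lo.median() > hi.median()


class TestMeanCv2Fit:
    def _table(self, x, y):
        return pd.DataFrame({"mu": x, "fit_x": x, "cv2": y,
                             "var_hat": np.nan, "fit_ok": True})

    def test_exact_linear_data_recovered_to_machine_precision(self):
        x = np.linspace(1.1, 9, 200)
        fit = ns.fit_mean_cv2(self._table(x, 2 + 3 / x))
        assert fit.a0 == pytest.approx(2, abs=1e-10)
        assert fit.a1 == pytest.approx(3, abs=1e-10)

    def test_printed_unit_curve_value(self):
        # with (a0, a1) = (1, 1) the expected CV2 at x = 2 is 1.5
        fit = ns.MeanCv2Fit(a0=1, a1=1, deviance=0, n_genes=0, n_iter=0,
                            converged=True)
        assert fit.expected(np.array([2.0]))[0] == 1.5

    def test_gamma_noise_recovery_within_three_se(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0.5, 8, 2000)
        y = rng.gamma(20.0, (1 + 1 / x) / 20.0)
        fit = ns.fit_mean_cv2(self._table(x, y))
        assert abs(fit.a0 - 1) < 3 * fit.se_a0
        assert abs(fit.a1 - 1) < 3 * fit.se_a1

    def test_too_few_genes_rejected(self):
        x = np.linspace(1, 5, 10)
        with pytest.raises(ValueError, match="genes"):
            ns.fit_mean_cv2(self._table(x, 1 + 1 / x))

    def test_outlier_rejection_stabilises_against_contamination(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.5, 8, 1000)
        y = 1 + 1 / x
        y[:50] = y[:50] * 30          # hyper-variable contamination
        fit = ns.fit_mean_cv2(self._table(x, y))
        assert fit.a0 == pytest.approx(1, rel=0.05)
        assert fit.a1 == pytest.approx(1, rel=0.05)


class TestResidualCv2:
    def test_zero_residual_when_on_curve(self):
        x = np.linspace(1.1, 5, 100)
        table = pd.DataFrame({"mu": x, "fit_x": x, "cv2": 2 + 3 / x,
                              "var_hat": np.nan, "fit_ok": True})
        out = ns.residual_cv2(table, 2, 3)
        assert np.allclose(out["rcv2"], 0)

    @pytest.mark.parametrize("cv2,expected_rcv2", [(5.0, 2.0), (1.0, 2.0)])
    def test_absolute_value_symmetry(self, cv2, expected_rcv2):
        table = pd.DataFrame({"mu": [2.0], "fit_x": [2.0], "cv2": [cv2],
                              "var_hat": np.nan, "fit_ok": [True]})
        out = ns.residual_cv2(table, 2.5, 1.0)   # expected = 3.0
        assert out["rcv2"].iloc[0] == pytest.approx(expected_rcv2)

    def test_excluded_genes_have_nan_rcv2(self):
        table = pd.DataFrame({"mu": [0.05, 3.0], "fit_x": [0.05, 3.0],
                              "cv2": [50.0, 1.2], "var_hat": np.nan,
                              "fit_ok": [False, True]})
        out = ns.residual_cv2(table, 1, 1)
        assert np.isnan(out["rcv2"].iloc[0])
        assert not np.isnan(out["rcv2"].iloc[1])
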