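"""Preprocessing contracts: the strict 10% missingness filter, KNN imputation
behaviour and accuracy, log2 transform, standardization."""

import numpy as np
import pandas as pd
import pytest

import metabyield as mb
from metabyield.preprocess import mean_impute

from conftest import matrix_from_values


def _rmse(a, b):
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


class TestMissingnessFilter:
    def test_strict_boundary_at_10_percent(self):
        vals = np.abs(np.random.default_rng(0).normal(10, 1, (10, 2))) + 1
        mask = np.zeros((10, 2), bool)
        mask[0, 0] = True  # 10% missing: kept
        mask[:2, 1] = True  # 20% missing: removed
        m = matrix_from_values(vals, mask)
        filtered, report = mb.filter_by_missingness(m, 0.10)
        assert filtered.metabolite_ids == ["M0"]
        assert report.removed_metabolites == ["M1"]

    def test_fraction_spectrum(self):
        n = 1000
        vals = np.abs(np.random.default_rng(1).normal(10, 1, (n, 4))) + 1
        mask = np.zeros((n, 4), bool)
        for j, miss in enumerate([0, 100, 101, 500]):  # fractions 0, .10, .101, .50
            mask[:miss, j] = True
        filtered, report = mb.filter_by_missingness(matrix_from_values(vals, mask), 0.10)
        assert len(report.removed_metabolites) == 2
        assert set(filtered.metabolite_ids) == {"M0", "M1"}

    def test_no_missing_is_identity(self, small_matrix):
        matrix, _ = small_matrix
        filtered, report = mb.filter_by_missingness(matrix)
        assert filtered.metabolite_ids == matrix.metabolite_ids
        assert report.removed_metabolites == []

    def test_report_partitions_columns(self, small_matrix):
        matrix, truth = small_matrix
        holey = mb.inject_missing(matrix, np.linspace(0, 0.4, matrix.n_metabolites), seed=2)
        _, report = mb.filter_by_missingness(holey)
        assert sorted(report.removed_metabolites + report.retained_metabolites) == sorted(
            matrix.metabolite_ids
        )

    def test_filter_impute_filter_idempotent(self, cell_scenario):
        matrix, truth, _ = cell_scenario
        holey = mb.inject_missing(matrix, truth.missing_rates, seed=6)
        filtered, _ = mb.filter_by_missingness(holey)
        imputed, _ = mb.knn_impute(filtered)
        again, report2 = mb.filter_by_missingness(imputed)
        assert report2.removed_metabolites == []
        assert again.metabolite_ids == imputed.metabolite_ids


class TestKnnImpute:
    def test_single_neighbour_copies_its_value(self):
        base = np.array([5.0, 7.0, 9.0, 11.0])
        vals = np.vstack([base, base, base + 5.0])
        mask = np.zeros_like(vals, bool)
        mask[0, 2] = True
        out, _ = mb.knn_impute(matrix_from_values(vals, mask), k=1)
        assert out.values.iloc[0, 2] == pytest.approx(vals[1, 2], rel=1e-9)

    def test_imputed_value_is_convex_combination(self):
        rng = np.random.default_rng(3)
        vals = np.abs(rng.normal(10, 2, (12, 5))) + 1
        mask = np.zeros_like(vals, bool)
        mask[0, 0] = True
        out, _ = mb.knn_impute(matrix_from_values(vals, mask), k=4)
        neighbours = vals[1:, 0]
        assert neighbours.min() - 1e-12 <= out.values.iloc[0, 0] <= neighbours.max() + 1e-12

    def test_observed_cells_bit_identical(self, cell_scenario):
        matrix, truth, _ = cell_scenario
        holey = mb.inject_missing(matrix, truth.missing_rates, seed=7)
        filtered, _ = mb.filter_by_missingness(holey)
        out, _ = mb.knn_impute(filtered)
        obs = ~filtered.mask.to_numpy()
        assert np.array_equal(out.values.to_numpy()[obs], filtered.values.to_numpy()[obs])
        assert out.is_complete()

    def test_beats_column_mean_on_correlated_data(self):
        """On block-correlated data, neighbours carry information a column
        mean cannot; compare masked-cell RMSE over several seeds."""
        wins = 0
        for seed in range(5):
            design = mb.build_design(5, 4, 3, organs=["flag_leaf"], stages=["anthesis"])
            matrix, _ = mb.simulate_metabolome(design, n_metabolites=30, n_blocks=5,
                                               block_rho=0.8, seed=seed, n_true_effects=0)
            holey = mb.inject_missing(matrix, np.full(30, 0.10), seed=seed)
            truth_vals = matrix.values.to_numpy()
            mask = holey.mask.to_numpy()
            knn_out, _ = mb.knn_impute(holey)
            mean_out = mean_impute(holey)
            if _rmse(knn_out.values.to_numpy()[mask], truth_vals[mask]) < _rmse(
                mean_out.values.to_numpy()[mask], truth_vals[mask]
            ):
                wins += 1
        assert wins >= 4

    def test_error_decreases_with_block_correlation(self):
        """Imputation error should trend downward as within-block correlation
        rises (more informative neighbours)."""
        mean_rmse = {}
        for rho in (0.0, 0.4, 0.8):
            errs = []
            for seed in range(8):
                design = mb.build_design(5, 4, 3, organs=["glume"], stages=["anthesis"])
                matrix, _ = mb.simulate_metabolome(design, n_metabolites=20, n_blocks=4,
                                                   block_rho=rho, seed=seed, n_true_effects=0)
                holey = mb.inject_missing(matrix, np.full(20, 0.10), seed=seed)
                mask = holey.mask.to_numpy()
                out, _ = mb.knn_impute(holey)
                # score on the log2 scale so errors are comparable across columns
                errs.append(_rmse(np.log2(out.values.to_numpy()[mask]),
                                  np.log2(matrix.values.to_numpy()[mask])))
            mean_rmse[rho] = np.mean(errs)
        assert mean_rmse[0.8] < mean_rmse[0.4] < mean_rmse[0.0] * 1.05
        assert mean_rmse[0.8] < mean_rmse[0.0]

    def test_column_median_fallback_when_no_neighbour_observes(self):
        vals = np.abs(np.random.default_rng(4).normal(10, 1, (10, 3))) + 1
        mask = np.zeros_like(vals, bool)
        mask[0, 1:] = True  # sample 0 observes only M0
        mask[1:, 0] = True  # everyone else misses M0
        # for any sample missing M0 the only candidate shares no observed
        # column with it → infinite distance → column-median fallback
        m = matrix_from_values(vals, mask)
        out, report = mb.knn_impute(m, k=3)
        assert out.is_complete()
        assert any("fallback" in w for w in report.warnings)


class TestLog2AndStandardize:
    def test_log2_known_values_and_roundtrip(self):
        vals = np.array([[8.0, 1.0], [2.0, 4.0]])
        m = matrix_from_values(vals)
        out = mb.log2_transform(m)
        assert out.scale == "log2"
        np.testing.assert_allclose(out.values.to_numpy(), [[3, 0], [1, 2]])
        np.testing.assert_allclose(2.0 ** out.values.to_numpy(), vals, rtol=1e-12)

    def test_log2_rejects_nonpositive_naming_cell(self):
        vals = np.array([[1.0, 2.0], [0.0, 3.0]])
        with pytest.raises(ValueError, match="S1.*M0"):
            mb.log2_transform(matrix_from_values(vals))

    def test_log2_rejects_wrong_scale(self):
        m = matrix_from_values(np.ones((3, 2)), scale="log2")
        with pytest.raises(ValueError, match="raw"):
            mb.log2_transform(m)

    def test_standardize_location_invariance_and_units(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(10, 2, (9, 3))
        shifted = vals + np.array([100.0, -50.0, 0.0])
        z1, _ = mb.standardize(matrix_from_values(vals))
        z2, _ = mb.standardize(matrix_from_values(shifted))
        np.testing.assert_allclose(z1.values.to_numpy(), z2.values.to_numpy(), atol=1e-12)
        col = matrix_from_values(np.array([[1.0], [2.0], [3.0]]))
        z3, _ = mb.standardize(col)
        np.testing.assert_allclose(z3.values.to_numpy().ravel(), [-1, 0, 1])

    def test_destandardized_ols_matches_raw_fit(self):
        """Coefficients mapped back through the scaler equal OLS on raw columns."""
        rng = np.random.default_rng(6)
        x = rng.normal(size=(10, 3)) * [1.0, 5.0, 0.2] + [3, -2, 7]
        y = rng.normal(size=10)
        m = matrix_from_values(np.abs(x) + 10)
        z, scaler = mb.standardize(m)
        zd = np.hstack([np.ones((10, 1)), z.values.to_numpy()])
        coef_std, *_ = np.linalg.lstsq(zd, y, rcond=None)
        beta, intercept = scaler.destandardize_coef(coef_std[1:], coef_std[0])
        xd = np.hstack([np.ones((10, 1)), m.values.to_numpy()])
        coef_raw, *_ = np.linalg.lstsq(xd, y, rcond=None)
        np.testing.assert_allclose(beta, coef_raw[1:], rtol=1e-8)
        assert intercept == pytest.approx(coef_raw[0], rel=1e-8)

    def test_standardize_rejects_constant_column(self):
        vals = np.ones((5, 2))
        vals[:, 1] = np.arange(5)
        with pytest.raises(ValueError, match="M0"):
            mb.standardize(matrix_from_values(vals))
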