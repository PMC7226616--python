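"""Resampling engine: split plans, per-run metrics, detection rates, and the
statistical sanity of the whole stability pipeline."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import metabyield as mb
from metabyield.stability import LassoConfig

from conftest import matrix_from_values

FAST_LASSO = LassoConfig(n_grid=40, eps=1e-2, cv_tol=1e-4)


class TestMakeSplits:
    def test_default_sizes(self):
        plan = mb.make_splits(60, seed=0)
        assert plan.n_runs == 100
        assert all(len(a) == 45 for a in plan.assignments)
        assert all(len(plan.validation(r)) == 15 for r in range(100))
        # train and validation partition the rows
        for r in (0, 57, 99):
            both = np.concatenate([plan.assignments[r], plan.validation(r)])
            assert sorted(both) == list(range(60))

    def test_deterministic_under_seed(self):
        p1 = mb.make_splits(50, n_runs=10, seed=42)
        p2 = mb.make_splits(50, n_runs=10, seed=42)
        for a, b in zip(p1.assignments, p2.assignments):
            np.testing.assert_array_equal(a, b)
        p3 = mb.make_splits(50, n_runs=10, seed=43)
        assert any(not np.array_equal(a, b) for a, b in zip(p1.assignments, p3.assignments))

    def test_stratified_preserves_condition_balance(self):
        strata = np.array(["WS"] * 30 + ["HY"] * 30)
        plan = mb.make_splits(60, n_runs=50, seed=1, stratify_by=strata)
        for a in plan.assignments:
            n_ws = int((strata[a] == "WS").sum())
            assert n_ws in (22, 23)
            assert len(a) == 45

    def test_kfold_mode_covers_every_sample_once_per_repetition(self):
        plan = mb.make_splits(60, n_runs=100, train_fraction=0.75, seed=2, mode="kfold")
        assert plan.n_runs == 100
        # consecutive groups of 4 runs (k = 1/(1-0.75) = 4) partition the rows
        for rep in range(3):
            vals = np.concatenate([plan.validation(4 * rep + i) for i in range(4)])
            assert sorted(vals) == list(range(60))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            mb.make_splits(60, train_fraction=1.2)
        with pytest.raises(ValueError):
            mb.make_splits(5)

    def test_roundtrip_serialization(self):
        plan = mb.make_splits(20, n_runs=5, seed=9)
        back = mb.SplitPlan.from_dict(plan.to_dict())
        for a, b in zip(plan.assignments, back.assignments):
            np.testing.assert_array_equal(a, b)


class TestAdjustedR2:
    def test_reference_value(self):
        assert mb.adjusted_r2(0.8, 100, 5) == pytest.approx(0.78936, abs=1e-5)

    def test_zero_parameters_is_identity(self):
        assert mb.adjusted_r2(0.37, 50, 0) == pytest.approx(0.37)

    @given(st.floats(0, 1), st.integers(5, 500), st.integers(0, 3))
    @settings(max_examples=50, deadline=None)
    def test_never_exceeds_raw(self, r2, n, p):
        adj = mb.adjusted_r2(r2, n, p)
        assert np.isnan(adj) or adj <= r2 + 1e-12

    def test_undefined_when_saturated(self):
        assert np.isnan(mb.adjusted_r2(0.9, 5, 4))


def test_predictive_ability_matches_pearson():
    rng = np.random.default_rng(0)
    y = rng.normal(size=40)
    pred = 0.6 * y + rng.normal(size=40)
    r, _ = scipy.stats.pearsonr(y, pred)
    assert mb.predictive_ability(y, pred) == pytest.approx(r**2, abs=1e-12)
    assert mb.predictive_ability(y, np.full(40, 3.0)) == 0.0


@pytest.fixture(scope="module")
def stability_on_signal(cell_scenario):
    matrix, truth, traits = cell_scenario
    logm = mb.log2_transform(matrix)
    plan = mb.make_splits(matrix.n_samples, n_runs=40, seed=21)
    res = mb.run_stability(logm, traits["GY"].to_numpy(), plan, FAST_LASSO)
    return res, truth


class TestRunStability:
    def test_detection_rate_bounds_and_bookkeeping(self, stability_on_signal):
        res, _ = stability_on_signal
        dr = res.detection_rate
        assert np.all((0 <= dr) & (dr <= 1))
        total_events = sum(m.n_selected for m in res.per_run)
        assert total_events == pytest.approx(dr.sum() * len(res.per_run))
        never = dr == 0
        assert np.all(res.mean_effect[never] == 0)
        for m in res.per_run:
            assert np.isnan(m.adj_r2_train) or m.adj_r2_train <= m.r2_train

    def test_true_features_dominate_detection(self, stability_on_signal):
        """Planted yield effects should be detected far more often than
        null metabolites on average."""
        res, truth = stability_on_signal
        true = truth.true_beta != 0
        assert res.detection_rate[true].mean() > res.detection_rate[~true].mean() + 0.3

    def test_duplicated_rows_leave_detection_unchanged(self):
        """Selection at a fixed penalty depends only on the empirical moments,
        which duplicating every row leaves unchanged (the 1/(2n) objective
        convention is scale-invariant in n)."""
        rng = np.random.default_rng(3)
        x = rng.normal(10, 2, size=(30, 8))
        y = 2.0 * x[:, 1] + rng.normal(size=30)
        cfg = LassoConfig(fixed_lambda=0.2)
        m1 = matrix_from_values(x)
        plan1 = mb.make_splits(30, n_runs=10, seed=4)
        res1 = mb.run_stability(m1, y, plan1, cfg)
        # duplicate every row; training sets pick both copies of each sample
        m2 = matrix_from_values(np.vstack([x, x]))
        plan2 = mb.SplitPlan(
            n_runs=10, train_fraction=0.75, seed=4, n_samples=60,
            assignments=[np.concatenate([a, a + 30]) for a in plan1.assignments],
        )
        res2 = mb.run_stability(m2, np.concatenate([y, y]), plan2, cfg)
        np.testing.assert_allclose(res1.detection_rate, res2.detection_rate)

    def test_permuted_response_destroys_recovery(self, cell_scenario):
        matrix, truth, traits = cell_scenario
        logm = mb.log2_transform(matrix)
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(500 + seed)
            y_perm = rng.permutation(traits["GY"].to_numpy())
            plan = mb.make_splits(matrix.n_samples, n_runs=30, seed=seed)
            res = mb.run_stability(logm, y_perm, plan, FAST_LASSO)
            if res.detection_rate.max() < 0.70:
                hits += 1
        assert hits >= 2

    def test_predictive_ability_increases_with_signal(self):
        """Mean predictive ability responds monotonically to the planted
        signal fraction."""
        means = []
        for r2_true in (None, 0.3, 0.7):
            pas = []
            for seed in range(3):
                matrix, truth, traits = mb.simulate_cell(
                    seed=700 + seed, n_metabolites=40,
                    n_true_effects=0 if r2_true is None else 10,
                    target_r2=r2_true, noise_sd=1.0,
                )
                logm = mb.log2_transform(matrix)
                plan = mb.make_splits(60, n_runs=25, seed=seed)
                res = mb.run_stability(logm, traits["GY"].to_numpy(), plan, FAST_LASSO)
                pas.append(res.summary["predictive_ability"])
            means.append(np.mean(pas))
        assert means[0] <= means[1] <= means[2]

    def test_serialization_roundtrip(self, stability_on_signal):
        res, _ = stability_on_signal
        d = res.to_dict()
        assert d["summary"]["predictive_ability"] == pytest.approx(
            np.mean([m.predictive_ability for m in res.per_run])
        )
        table = res.effects_table()
        assert list(table.columns) == [
            "metabolite", "detection_rate", "mean_effect", "mean_effect_selected"
        ]
        assert (table["detection_rate"].diff().dropna() <= 1e-12).all()


class TestCompareScales:
    def test_log_generated_yield_prefers_log2_scale(self):
        """Yield built from log2 intensities over a wide dynamic range is
        predicted better on the log2 scale."""
        prefs = []
        for seed in range(2):
            matrix, truth, traits = mb.simulate_cell(
                seed=900 + seed, n_metabolites=30, n_true_effects=5,
                target_r2=0.8, intensity_sd=2.5,
            )
            plan = mb.make_splits(60, n_runs=20, seed=seed)
            rec, _ = mb.compare_scales(matrix, traits["GY"].to_numpy(), plan, FAST_LASSO)
            prefs.append(rec)
        assert prefs.count("log2") >= 1

    def test_degenerate_constant_matrix_ties_toward_raw(self, caplog):
        vals = np.full((20, 4), 7.0)
        m = matrix_from_values(vals)
        plan = mb.make_splits(20, n_runs=5, seed=0)
        y = np.random.default_rng(1).normal(size=20)
        rec, results = mb.compare_scales(m, y, plan, FAST_LASSO)
        assert rec == "raw"
        assert results["raw"].summary["predictive_ability"] == 0.0
        assert results["log2"].summary["predictive_ability"] == 0.0
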