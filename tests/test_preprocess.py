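import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from probstack.preprocess import (
    DegenerateLabelError,
    PreprocessConfig,
    UnimputableColumnError,
    apply_scalers,
    detect_outliers,
    fit_scalers,
    impute_nulls,
    rebalance,
    remove_duplicates,
    run_pipeline,
)
from probstack.schema import SemanticType

from conftest import make_dataset


class TestRemoveDuplicates:
    def test_rows_one_and_three_identical(self):
        ds = make_dataset([[1, 2], [3, 4], [1, 2]], [1, 0, 1])
        out, count = remove_duplicates(ds)
        assert count == 1
        assert out.n_rows == 2

    def test_all_distinct_identity(self):
        ds = make_dataset([[1, 2], [3, 4], [5, 6]], [1, 0, 1])
        out, count = remove_duplicates(ds)
        assert count == 0
        assert out.n_rows == 3

    def test_three_copies_brute_force(self):
        X = np.array(
            [[0, 0], [1, 0], [2, 0], [3, 0], [4, 0], [5, 0], [6, 0], [7, 0]],
            dtype=float,
        )
        X = np.vstack([X, X[0], X[0]])  # 3 copies of row 0 -> 10 rows
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 1])
        ds = make_dataset(X, y)
        # brute-force oracle: pairwise comparison, count later twins
        rows = [tuple(X[i]) + (y[i],) for i in range(len(X))]
        expected = sum(
            any(rows[i] == rows[j] for j in range(i)) for i in range(len(rows))
        )
        out, count = remove_duplicates(ds)
        assert count == expected == 2
        assert out.n_rows == 8

    def test_same_features_different_label_kept(self):
        ds = make_dataset([[1, 2], [1, 2]], [0, 1])
        _, count = remove_duplicates(ds)
        assert count == 0

    def test_survivor_order_preserved(self):
        ds = make_dataset([[9, 9], [1, 1], [9, 9], [2, 2]], [1, 0, 1, 0])
        out, _ = remove_duplicates(ds)
        np.testing.assert_array_equal(
            out.values.to_numpy(), [[9, 9], [1, 1], [2, 2]]
        )


class TestImputeNulls:
    def test_no_missing_identity(self):
        ds = make_dataset([[1, 2], [3, 4]], [0, 1])
        out, count = impute_nulls(ds, PreprocessConfig())
        assert count == 0
        pd.testing.assert_frame_equal(out.values, ds.values)

    def test_label_distribution_mode_fills_class_mean(self):
        X = np.array([[10.0, 1], [np.nan, 1], [30.0, 1], [50.0, 1]])
        y = np.array([0, 0, 0, 1])
        ds = make_dataset(X, y)
        out, count = impute_nulls(
            ds, PreprocessConfig(impute_method="label_distribution")
        )
        assert count == 1
        # class-0 mean of f0 over observed rows = (10 + 30) / 2
        assert out.values.iloc[1, 0] == pytest.approx(20.0)

    def test_knn_fill_matches_exhaustive_neighbor_search(self):
        # hand-built 4-row table; the missing cell must equal the mean of
        # the 2 nearest fully observed rows by exhaustive enumeration
        X = np.array(
            [
                [0.0, 0.0, 5.0],
                [0.1, 0.1, 7.0],
                [10.0, 10.0, 100.0],
                [0.05, 0.0, np.nan],
            ]
        )
        y = np.array([0, 1, 0, 1])
        ds = make_dataset(X, y)
        out, count = impute_nulls(ds, PreprocessConfig(impute_method="knn", knn_k=2))
        assert count == 1
        complete = [0, 1, 2]
        target = X[3, :2]
        dists = sorted(
            complete, key=lambda i: float(np.sum((X[i, :2] - target) ** 2))
        )
        expected = np.mean([X[i, 2] for i in dists[:2]])
        assert out.values.iloc[3, 2] == pytest.approx(expected)
        assert expected == pytest.approx(6.0)

    def test_entirely_missing_column_errors(self):
        X = np.array([[np.nan, 1.0], [np.nan, 2.0]])
        ds = make_dataset(X, [0, 1])
        with pytest.raises(UnimputableColumnError):
            impute_nulls(ds, PreprocessConfig())

    def test_zero_missing_after(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 4))
        X[rng.random(X.shape) < 0.1] = np.nan
        ds = make_dataset(X, rng.integers(0, 2, 50))
        for method in ("knn", "label_distribution"):
            out, _ = impute_nulls(ds, PreprocessConfig(impute_method=method))
            assert out.n_missing() == 0


class TestDetectOutliers:
    def test_contamination_zero_empty_mask(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.normal(size=(50, 3)), rng.integers(0, 2, 50))
        mask = detect_outliers(ds, PreprocessConfig(contamination=0.0))
        assert mask.dtype == bool and not mask.any()

    def test_isolation_forest_flags_displaced_point(self):
        # 100 clustered rows + 1 point displaced 10 SDs; the flagged row
        # must be the max-Mahalanobis-distance point (brute force check)
        rng = np.random.default_rng(11)
        X = rng.normal(size=(100, 3))
        X = np.vstack([X, [10.0, 10.0, 10.0]])
        y = rng.integers(0, 2, 101)
        ds = make_dataset(X, y)
        mask = detect_outliers(
            ds, PreprocessConfig(contamination=0.01, seed=0)
        )
        assert mask.sum() == 1
        cov_inv = np.linalg.inv(np.cov(X.T))
        mu = X.mean(axis=0)
        d2 = np.einsum("ij,jk,ik->i", X - mu, cov_inv, X - mu)
        assert int(np.flatnonzero(mask)[0]) == int(np.argmax(d2)) == 100

    def test_zscore_hand_computed(self):
        # n=5 bounds |z| by (n-1)/sqrt(n) ~ 1.79, so use a threshold the
        # displaced point actually exceeds; z(100) = (100-20)/40 = 2.0
        x = np.array([[0.0], [0.0], [0.0], [0.0], [100.0]])
        ds = make_dataset(x, [0, 1, 0, 1, 0])
        z_last = (100 - x.mean()) / x.std()
        assert z_last == pytest.approx(2.0)
        mask = detect_outliers(
            ds, PreprocessConfig(outlier_method="zscore", zscore_threshold=1.9)
        )
        np.testing.assert_array_equal(mask, [False, False, False, False, True])

    def test_isolation_forest_needs_eight_rows(self):
        ds = make_dataset(np.zeros((4, 2)), [0, 1, 0, 1])
        with pytest.raises(ValueError):
            detect_outliers(ds, PreprocessConfig(contamination=0.25))

    def test_mask_length(self):
        rng = np.random.default_rng(2)
        ds = make_dataset(rng.normal(size=(40, 2)), rng.integers(0, 2, 40))
        mask = detect_outliers(ds, PreprocessConfig(contamination=0.1))
        assert len(mask) == 40


class TestRebalance:
    def _imbalanced(self, n0=60, n1=40):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(n0 + n1, 2))
        y = np.array([0] * n0 + [1] * n1)
        return make_dataset(X, y)

    def test_oversample(self):
        out = rebalance(self._imbalanced(), PreprocessConfig(rebalance_method="oversample"))
        assert np.bincount(out.labels).tolist() == [60, 60]

    def test_undersample(self):
        out = rebalance(self._imbalanced(), PreprocessConfig(rebalance_method="undersample"))
        assert np.bincount(out.labels).tolist() == [40, 40]

    def test_already_balanced_identity(self):
        ds = self._imbalanced(50, 50)
        out = rebalance(ds, PreprocessConfig(rebalance_method="oversample"))
        assert out.n_rows == 100

    def test_none_identity(self):
        ds = self._imbalanced()
        assert rebalance(ds, PreprocessConfig()) is ds

    def test_single_class_errors(self):
        ds = make_dataset(np.zeros((4, 1)), [1, 1, 1, 1])
        with pytest.raises(DegenerateLabelError):
            rebalance(ds, PreprocessConfig(rebalance_method="oversample"))

    def test_seeded_determinism(self):
        ds = self._imbalanced()
        cfg = PreprocessConfig(rebalance_method="oversample", seed=9)
        a = rebalance(ds, cfg)
        b = rebalance(ds, cfg)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestScalers:
    def test_normal_column_standardized(self):
        rng = np.random.default_rng(0)
        x = rng.normal(50, 10, size=500)
        ds = make_dataset(x[:, None], rng.integers(0, 2, 500))
        cfg = PreprocessConfig()
        plan = fit_scalers(ds, cfg)
        assert plan.transforms["f0"].kind == "standardized"
        out = apply_scalers(ds, plan)
        assert out.values["f0"].mean() == pytest.approx(0.0, abs=1e-9)
        assert out.values["f0"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_non_normal_column_max_scaled(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, size=500) ** 4  # heavy right skew
        # decision must agree with the declared normality test
        assert stats.normaltest(x).pvalue <= 0.05
        ds = make_dataset(x[:, None], rng.integers(0, 2, 500))
        plan = fit_scalers(ds, PreprocessConfig())
        assert plan.transforms["f0"].kind == "max_scaled"
        out = apply_scalers(ds, plan)
        assert 0 <= out.values["f0"].min() and out.values["f0"].max() == pytest.approx(1.0)

    def test_constant_column_zeroed(self):
        ds = make_dataset(np.full((30, 1), 7.0), np.tile([0, 1], 15))
        plan = fit_scalers(ds, PreprocessConfig())
        assert plan.transforms["f0"].kind == "constant"
        out = apply_scalers(ds, plan)
        assert (out.values["f0"] == 0).all()

    def test_binary_column_untouched(self):
        rng = np.random.default_rng(2)
        ds = make_dataset(
            rng.integers(0, 2, size=(40, 1)).astype(float),
            rng.integers(0, 2, 40),
            kind=SemanticType.BINARY,
        )
        plan = fit_scalers(ds, PreprocessConfig())
        assert plan.transforms["f0"].kind == "untouched"
        out = apply_scalers(ds, plan)
        pd.testing.assert_frame_equal(out.values, ds.values)

    def test_skewed_normal_log_transformed(self):
        rng = np.random.default_rng(3)
        x = np.exp(rng.normal(0, 0.6, size=800))  # lognormal: skewed
        ds = make_dataset(x[:, None], rng.integers(0, 2, 800))
        plan = fit_scalers(ds, PreprocessConfig())
        # lognormal fails the normality gate -> max-scaled, OR in the rare
        # normal-pass case it must be caught by the skew rule
        assert plan.transforms["f0"].kind in ("max_scaled", "log_standardized")

    def test_frozen_plan_applied_to_unseen_rows(self):
        rng = np.random.default_rng(4)
        train = make_dataset(rng.normal(10, 2, size=(200, 1)), rng.integers(0, 2, 200))
        test = make_dataset(rng.normal(10, 2, size=(50, 1)), rng.integers(0, 2, 50))
        plan = fit_scalers(train, PreprocessConfig())
        t = plan.transforms["f0"]
        out = apply_scalers(test, plan)
        expected = (test.values["f0"] - t.mean) / t.std
        pd.testing.assert_series_equal(out.values["f0"], expected)


class TestRunPipeline:
    def _messy(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(120, 3))
        y = rng.integers(0, 2, 120)
        X = np.vstack([X, X[:5]])  # duplicates
        y = np.concatenate([y, y[:5]])
        X[10, 0] = np.nan
        X[20, 2] = np.nan
        return make_dataset(X, y)

    def test_counts_consistent_with_row_deltas(self):
        ds = self._messy()
        cfg = PreprocessConfig(contamination=0.05, rebalance_method="oversample", seed=0)
        out, plan, report = run_pipeline(ds, cfg)
        assert report.duplicates_removed == 5
        assert report.cells_imputed == 2
        n_after_dupes = 120
        n_after_outliers = n_after_dupes - report.outliers_removed
        counts = np.bincount(out.labels)
        assert counts[0] == counts[1]  # oversampled
        assert out.n_rows >= n_after_outliers
        assert out.n_missing() == 0

    def test_every_numeric_column_has_one_transform(self):
        ds = self._messy()
        _, plan, report = run_pipeline(ds, PreprocessConfig())
        assert set(report.column_transforms) == {"f0", "f1", "f2"}

    def test_byte_determinism(self):
        cfg = PreprocessConfig(
            contamination=0.05, rebalance_method="oversample", seed=123
        )
        a, _, _ = run_pipeline(self._messy(), cfg)
        b, _, _ = run_pipeline(self._messy(), cfg)
        pd.testing.assert_frame_equal(a.values, b.values)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestConfigValidation:
    def test_contamination_bounds(self):
        with pytest.raises(ValueError):
            PreprocessConfig(contamination=0.6)

    def test_knn_k_positive(self):
        with pytest.raises(ValueError):
            PreprocessConfig(knn_k=0)
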