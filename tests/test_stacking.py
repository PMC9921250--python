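import itertools

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from probstack.models import default_config, predict_base, train_base, FittedBaseModel
from probstack.stacking import (
    EnsembleMismatchError,
    StackedModel,
    StratificationError,
    _oof_base_outputs,
    build_meta_features,
    fit_classical_stack,
    fit_stacked,
    majority_vote,
    predict_stacked,
)

from conftest import make_dataset


def fake_outputs(model_ids, n, seed=0):
    rng = np.random.default_rng(seed)
    out = {}
    for m in model_ids:
        p = rng.random(n)
        out[m] = ((p >= 0.5).astype(int), p)
    return out


class TestBuildMetaFeatures:
    def test_six_models_width_twelve(self):
        outputs = fake_outputs([f"m{i}" for i in range(6)], 100)
        mf = build_meta_features(outputs, tuple(outputs))
        assert mf.matrix.shape == (100, 12)

    def test_single_model_single_row(self):
        mf = build_meta_features(
            {"m": (np.array([1]), np.array([0.9]))}, ("m",)
        )
        np.testing.assert_allclose(mf.matrix, [[1.0, 0.9]])

    def test_missing_model_rejected(self):
        outputs = fake_outputs(["a"], 10)
        with pytest.raises(EnsembleMismatchError):
            build_meta_features(outputs, ("a", "b"))

    def test_order_permutation_round_trip(self):
        outputs = fake_outputs(["a", "b", "c"], 50, seed=3)
        for perm in itertools.permutations(["a", "b", "c"]):
            mf = build_meta_features(outputs, perm)
            for i, m in enumerate(perm):
                np.testing.assert_array_equal(mf.matrix[:, 2 * i], outputs[m][0])
                np.testing.assert_array_equal(mf.matrix[:, 2 * i + 1], outputs[m][1])


class TestMajorityVote:
    def test_even_tie_broken_by_mean_probability(self):
        outputs = {
            f"m{i}": (np.array([c]), np.array([p]))
            for i, (c, p) in enumerate(
                [(1, 0.9), (1, 0.8), (1, 0.9), (0, 0.4), (0, 0.6), (0, 0.6)]
            )
        }
        # 3 vs 3, mean p = 0.7 -> class 1
        assert majority_vote(outputs)[0] == 1

    def test_strict_majority(self):
        outputs = {
            "a": (np.array([1]), np.array([0.6])),
            "b": (np.array([1]), np.array([0.7])),
            "c": (np.array([0]), np.array([0.1])),
        }
        assert majority_vote(outputs)[0] == 1

    def test_double_tie_goes_to_class_one(self):
        outputs = {
            "a": (np.array([1]), np.array([0.9])),
            "b": (np.array([0]), np.array([0.1])),
        }
        # 1 vs 1 and mean p exactly 0.5 -> class 1
        assert majority_vote(outputs)[0] == 1

    def test_exhaustive_oracle_m6(self):
        rng = np.random.default_rng(0)
        for pattern in itertools.product([0, 1], repeat=6):
            probs = np.where(
                np.array(pattern) == 1, rng.uniform(0.5, 1, 6), rng.uniform(0, 0.5, 6)
            )
            outputs = {
                f"m{i}": (np.array([c]), np.array([p]))
                for i, (c, p) in enumerate(zip(pattern, probs))
            }
            ones = sum(pattern)
            if ones > 3:
                expected = 1
            elif ones < 3:
                expected = 0
            else:
                expected = int(probs.mean() >= 0.5)
            assert majority_vote(outputs)[0] == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            majority_vote({})


class _StubEstimator:
    """predict_proba returns a fixed positive probability for every row."""

    classes_ = np.array([0, 1])

    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        pos = np.full(len(X), self.p)
        return np.column_stack([1 - pos, pos])


def _stub_model(name, p, n_features=2):
    return FittedBaseModel(
        model_id="lr",
        estimator=_StubEstimator(p),
        feature_names=tuple(f"f{i}" for i in range(n_features)),
        config=default_config("lr"),
    )


class TestFitStacked:
    def test_perfect_oracle_base_gives_perfect_stack(self, separable_dataset):
        sm = fit_stacked(
            separable_dataset, {"lr": default_config("lr")}, oof_folds=5, seed=0
        )
        cls, _ = predict_stacked(sm, separable_dataset.feature_matrix())
        assert (cls == separable_dataset.labels).mean() == 1.0

    def test_constant_base_predicts_majority_class(self):
        # all bases emit class 0 with p=0.2; labels are 70% zeros
        rng = np.random.default_rng(1)
        n = 100
        y = (rng.random(n) < 0.3).astype(int)
        X = rng.normal(size=(n, 2))
        bases = {"a": _stub_model("a", 0.2), "b": _stub_model("b", 0.2)}
        outputs = {m: (np.zeros(n, dtype=int), np.full(n, 0.2)) for m in bases}
        mf = build_meta_features(outputs, ("a", "b"))
        meta = LogisticRegression(max_iter=1000).fit(mf.matrix, y)
        sm = StackedModel(
            base_models=bases,
            meta=meta,
            model_order=("a", "b"),
            meta_width=4,
            oof_folds=5,
            seed=0,
        )
        cls, _ = predict_stacked(sm, X)
        assert (cls == 0).all()

    def test_oof_matrix_matches_manual_fold_loop(self):
        rng = np.random.default_rng(0)
        n = 200
        X = rng.normal(size=(n, 4))
        y = (rng.random(n) < 1 / (1 + np.exp(-X[:, 0]))).astype(int)
        ds = make_dataset(X, y)
        cfgs = {"lr": default_config("lr"), "rf": default_config("rf")}
        oof = _oof_base_outputs(ds, cfgs, oof_folds=5, seed=42)

        # independent reconstruction: same declared protocol, separate code
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=42)
        for name, cfg in cfgs.items():
            cls_exp = np.empty(n, dtype=int)
            p_exp = np.empty(n)
            for tr, te in skf.split(X, y):
                fold_ds = make_dataset(X[tr], y[tr])
                model = train_base(fold_ds, cfg)
                c, p = predict_base(model, X[te])
                cls_exp[te], p_exp[te] = c, p
            np.testing.assert_array_equal(oof[name][0], cls_exp)
            np.testing.assert_allclose(oof[name][1], p_exp)

    def test_oof_protocol_recorded(self, separable_dataset):
        sm = fit_stacked(separable_dataset, {"lr": default_config("lr")}, oof_folds=4, seed=9)
        assert sm.oof_folds == 4 and sm.seed == 9

    def test_stratification_error_when_class_too_small(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        ds = make_dataset(X, y)
        with pytest.raises(StratificationError):
            fit_stacked(ds, {"lr": default_config("lr")}, oof_folds=3)

    def test_oof_folds_minimum(self, separable_dataset):
        with pytest.raises(ValueError):
            fit_stacked(separable_dataset, {"lr": default_config("lr")}, oof_folds=1)


class TestPredictStacked:
    def test_zero_meta_coefficients_give_half(self):
        bases = {"a": _stub_model("a", 0.8)}
        meta = LogisticRegression()
        meta.classes_ = np.array([0, 1])
        meta.coef_ = np.array([[0.0, 0.0]])
        meta.intercept_ = np.array([0.0])
        sm = StackedModel(bases, meta, ("a",), 2, 5, 0)
        _, p = predict_stacked(sm, np.zeros((4, 2)))
        np.testing.assert_allclose(p, 0.5)

    def test_hand_set_meta_closed_form(self):
        # meta logit = w_c*class + w_p*p + b on a 1-model ensemble
        w_c, w_p, b = 0.7, -1.3, 0.2
        base_p = 0.8
        bases = {"a": _stub_model("a", base_p)}
        meta = LogisticRegression()
        meta.classes_ = np.array([0, 1])
        meta.coef_ = np.array([[w_c, w_p]])
        meta.intercept_ = np.array([b])
        sm = StackedModel(bases, meta, ("a",), 2, 5, 0)
        _, p = predict_stacked(sm, np.zeros((1, 2)))
        expected = 1 / (1 + np.exp(-(w_c * 1 + w_p * base_p + b)))
        assert p[0] == pytest.approx(expected, abs=1e-12)

    def test_probability_class_consistency(self, separable_dataset):
        sm = fit_stacked(
            separable_dataset,
            {"lr": default_config("lr"), "rf": default_config("rf")},
            oof_folds=3,
        )
        cls, p = predict_stacked(sm, separable_dataset.feature_matrix())
        np.testing.assert_array_equal(cls, (p >= 0.5).astype(int))

    def test_width_mismatch_rejected(self, separable_dataset):
        sm = fit_stacked(separable_dataset, {"lr": default_config("lr")}, oof_folds=3)
        sm.meta_width = 99
        with pytest.raises(EnsembleMismatchError):
            predict_stacked(sm, separable_dataset.feature_matrix())


class TestClassicalStack:
    def test_meta_width_is_m(self, separable_dataset):
        cfgs = {"lr": default_config("lr"), "rf": default_config("rf")}
        classical = fit_classical_stack(separable_dataset, cfgs, oof_folds=3)
        proposed = fit_stacked(separable_dataset, cfgs, oof_folds=3)
        assert classical.meta_width == 2
        assert proposed.meta_width == 4

    def test_single_model_stack_tracks_base_accuracy(self, noisy_dataset):
        # M=1: the meta layer can learn the identity mapping, so stacked
        # CV accuracy stays within 2pp of the base model's
        from probstack.evaluate import PipelineSpec, compare_combiners
        from probstack.preprocess import PreprocessConfig

        spec = PipelineSpec(
            base_cfgs={"lr": default_config("lr")},
            preprocess=PreprocessConfig(contamination=0.0),
            oof_folds=3,
        )
        res = compare_combiners(
            noisy_dataset, spec, k=5, seed=0, combiners=("proposed", "single:lr")
        )
        assert (
            res["proposed"].mean_metrics["accuracy"]
            >= res["single:lr"].mean_metrics["accuracy"] - 0.02
        )
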