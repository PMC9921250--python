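"""Probability-augmented stacking, plus the two baseline combiners.

The meta layer is a logistic model trained on each base model's class
decision AND its positive-class probability (2M columns for M bases).
Meta-features for training rows are produced out-of-fold by default, so
no base model scores a row it was trained on; the classical
classes-only stacker and a majority-vote combiner are provided as
baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .models import BaseModelConfig, FittedBaseModel, predict_base, train_base
from .schema import TabularDataset

__all__ = [
    "MetaFeatures",
    "StackedModel",
    "BaseOutputs",
    "build_meta_features",
    "fit_stacked",
    "fit_classical_stack",
    "predict_stacked",
    "majority_vote",
    "EnsembleMismatchError",
    "StratificationError",
]

#: per-model (class vector, positive probability vector)
BaseOutputs = dict[str, tuple[np.ndarray, np.ndarray]]


class EnsembleMismatchError(ValueError):
    """Outputs/rows do not match the ensemble's model order or width."""


class StratificationError(ValueError):
    """A CV fold cannot hold both classes."""


@dataclass(frozen=True)
class MetaFeatures:
    """n_rows × 2M matrix laid out (class_1, p_1, ..., class_M, p_M)."""

    matrix: np.ndarray
    model_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != 2 * len(self.model_order):
            raise EnsembleMismatchError("meta matrix width must be 2 x n_models")


@dataclass
class StackedModel:
    base_models: dict[str, FittedBaseModel]
    meta: LogisticRegression
    model_order: tuple[str, ...]
    meta_width: int
    oof_folds: int
    seed: int
    probability_features: bool = True


def build_meta_features(outputs: BaseOutputs, model_order: tuple[str, ...]) -> MetaFeatures:
    """Assemble the 2M-wide meta matrix in ``model_order`` layout."""
    missing = [m for m in model_order if m not in outputs]
    if missing:
        raise EnsembleMismatchError(f"missing base model outputs: {missing}")
    cols = []
    for m in model_order:
        cls, p = outputs[m]
        cols.append(np.asarray(cls, dtype=float))
        cols.append(np.asarray(p, dtype=float))
    return MetaFeatures(matrix=np.column_stack(cols), model_order=tuple(model_order))


def _classes_only(mf: MetaFeatures) -> np.ndarray:
    return mf.matrix[:, 0::2]


def _oof_base_outputs(
    ds: TabularDataset,
    base_cfgs: dict[str, BaseModelConfig],
    oof_folds: int,
    seed: int,
) -> BaseOutputs:
    """Out-of-fold (class, probability) per base model over the training rows."""
    y = ds.labels
    if np.bincount(y, minlength=2).min() < oof_folds:
        raise StratificationError(
            f"each class needs >= {oof_folds} members for {oof_folds}-fold stacking"
        )
    skf = StratifiedKFold(n_splits=oof_folds, shuffle=True, random_state=seed)
    X = ds.feature_matrix()
    outputs: BaseOutputs = {
        m: (np.empty(ds.n_rows, dtype=int), np.empty(ds.n_rows)) for m in base_cfgs
    }
    for tr, te in skf.split(X, y):
        fold_ds = ds.replace(
            values=ds.values.iloc[tr].reset_index(drop=True), labels=y[tr]
        )
        for name, cfg in base_cfgs.items():
            model = train_base(fold_ds, cfg)
            cls, p = predict_base(model, X[te])
            outputs[name][0][te] = cls
            outputs[name][1][te] = p
    return outputs


def _fit_meta(
    ds: TabularDataset,
    base_cfgs: dict[str, BaseModelConfig],
    oof_folds: int,
    seed: int,
    probability_features: bool,
    in_sample: bool,
) -> StackedModel:
    if oof_folds < 2:
        raise ValueError("oof_folds must be >= 2")
    model_order = tuple(base_cfgs)
    # deployment bases are fit on all training rows
    fitted = {name: train_base(ds, cfg) for name, cfg in base_cfgs.items()}
    if in_sample:
        outputs = {name: predict_base(m, ds.feature_matrix()) for name, m in fitted.items()}
    else:
        outputs = _oof_base_outputs(ds, base_cfgs, oof_folds, seed)
    mf = build_meta_features(outputs, model_order)
    Xm = mf.matrix if probability_features else _classes_only(mf)
    meta = LogisticRegression(max_iter=2000, random_state=seed).fit(Xm, ds.labels)
    return StackedModel(
        base_models=fitted,
        meta=meta,
        model_order=model_order,
        meta_width=Xm.shape[1],
        oof_folds=oof_folds,
        seed=seed,
        probability_features=probability_features,
    )


def fit_stacked(
    ds: TabularDataset,
    base_cfgs: dict[str, BaseModelConfig],
    oof_folds: int = 5,
    seed: int = 0,
    in_sample: bool = False,
) -> StackedModel:
    """Probability-augmented stacker (meta width 2M).

    ``in_sample=True`` trains the meta layer on the deployment bases' own
    training-set predictions (leaky; provided for protocol comparison).
    """
    return _fit_meta(ds, base_cfgs, oof_folds, seed, True, in_sample)


def fit_classical_stack(
    ds: TabularDataset,
    base_cfgs: dict[str, BaseModelConfig],
    oof_folds: int = 5,
    seed: int = 0,
    in_sample: bool = False,
) -> StackedModel:
    """Classes-only baseline stacker (meta width M)."""
    return _fit_meta(ds, base_cfgs, oof_folds, seed, False, in_sample)


def stacked_base_outputs(sm: StackedModel, rows) -> BaseOutputs:
    return {name: predict_base(m, rows) for name, m in sm.base_models.items()}


def predict_stacked(sm: StackedModel, rows) -> tuple[np.ndarray, np.ndarray]:
    """Meta-logistic decision at threshold 0.5 plus its probability."""
    outputs = stacked_base_outputs(sm, rows)
    mf = build_meta_features(outputs, sm.model_order)
    Xm = mf.matrix if sm.probability_features else _classes_only(mf)
    if Xm.shape[1] != sm.meta_width:
        raise EnsembleMismatchError(
            f"meta width {Xm.shape[1]} != training width {sm.meta_width}"
        )
    pos = int(np.flatnonzero(sm.meta.classes_ == 1)[0])
    p = sm.meta.predict_proba(Xm)[:, pos]
    return (p >= 0.5).astype(int), p


def majority_vote(outputs: BaseOutputs) -> np.ndarray:
    """Per-row class with the strictly greater decision count.

    An even split is broken by the higher mean positive probability; if
    that mean is exactly 0.5, class 1 wins.
    """
    if not outputs:
        raise ValueError("outputs must contain at least one model")
    classes = np.column_stack([np.asarray(c) for c, _ in outputs.values()])
    probs = np.column_stack([np.asarray(p) for _, p in outputs.values()])
    ones = classes.sum(axis=1)
    zeros = classes.shape[1] - ones
    result = np.where(ones > zeros, 1, 0)
    tie = ones == zeros
    if tie.any():
        result[tie] = (probs[tie].mean(axis=1) >= 0.5).astype(int)
    return result.astype(int)
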