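"""Confusion-matrix metrics, stratified k-fold protocol and comparison reports.

Metrics are the five classics (accuracy, specificity, sensitivity,
precision, F1) recomputed exactly from confusion counts; zero-denominator
ratios are reported as ``None`` (undefined), never coerced to 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .models import BaseModelConfig, predict_base, train_base
from .preprocess import (
    PreprocessConfig,
    apply_scalers,
    detect_outliers,
    drop_rows,
    fit_scalers,
    impute_nulls,
    rebalance,
    remove_duplicates,
)
from .schema import TabularDataset
from .stacking import (
    StratificationError,
    _classes_only,
    _oof_base_outputs,
    build_meta_features,
    majority_vote,
)
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "EvaluationMetrics",
    "CVResult",
    "PipelineSpec",
    "confusion",
    "metrics",
    "stratified_kfold",
    "cross_validate",
    "compare_combiners",
    "compare_frameworks",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EvaluationMetrics:
    accuracy: float
    specificity: float | None
    sensitivity: float | None
    precision: float | None
    f1: float | None
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "f1": self.f1,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "tn": self.counts.tn,
        }


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count tp/fp/fn/tn with positive class = 1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for v in (y_true, y_pred):
        if not np.isin(v, [0, 1]).all():
            raise ValueError("labels must be binary (0/1)")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(c: ConfusionCounts) -> EvaluationMetrics:
    """accuracy=(TP+TN)/N, specificity=TN/(FP+TN), sensitivity=TP/(FN+TP),
    precision=TP/(TP+FP), f1 = harmonic mean of sensitivity and precision."""
    if c.n < 1:
        raise ValueError("N must be >= 1")
    accuracy = (c.tp + c.tn) / c.n
    specificity = _ratio(c.tn, c.fp + c.tn)
    sensitivity = _ratio(c.tp, c.fn + c.tp)
    precision = _ratio(c.tp, c.tp + c.fp)
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f1 = None
    else:
        f1 = 2 * sensitivity * precision / (sensitivity + precision)
    return EvaluationMetrics(
        accuracy=accuracy,
        specificity=specificity,
        sensitivity=sensitivity,
        precision=precision,
        f1=f1,
        counts=c,
    )


def stratified_kfold(ds: TabularDataset, k: int, seed: int) -> np.ndarray:
    """Row → fold-id map; folds are disjoint, exhaustive and stratified."""
    y = ds.labels
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.bincount(y, minlength=2).min() < k:
        raise StratificationError(f"each class needs >= {k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[te] = fold
    return assignment


# ---------------------------------------------------------------------------
# Cross-validated pipeline evaluation
# ---------------------------------------------------------------------------

Combiner = Literal["proposed", "classical", "majority"]


@dataclass
class PipelineSpec:
    """Everything cross_validate needs to run one fold end to end."""

    base_cfgs: dict[str, BaseModelConfig]
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    combiner: str = "proposed"  # proposed | classical | majority | single:<id>
    oof_folds: int = 5
    in_sample_meta: bool = False


@dataclass
class CVResult:
    k: int
    per_fold: list[EvaluationMetrics]
    mean_metrics: dict[str, float | None]
    fold_assignment: np.ndarray
    seed: int


def _mean_metrics(per_fold: list[EvaluationMetrics]) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    for name in ("accuracy", "specificity", "sensitivity", "precision", "f1"):
        vals = [getattr(m, name) for m in per_fold]
        defined = [v for v in vals if v is not None]
        if len(defined) < len(vals):
            warnings.warn(
                f"metric {name!r} undefined in {len(vals) - len(defined)} fold(s); "
                "excluded from the mean"
            )
        out[name] = float(np.mean(defined)) if defined else None
    return out


def _prepare_fold(
    ds: TabularDataset, train_idx: np.ndarray, test_idx: np.ndarray, cfg: PreprocessConfig
) -> tuple[TabularDataset, TabularDataset]:
    """Fit fold-local preprocessing on the training partition only.

    Outlier removal and rebalancing touch training rows only; the frozen
    scaler plan is reapplied verbatim to the held-out rows.
    """
    train = ds.replace(
        values=ds.values.iloc[train_idx].reset_index(drop=True),
        labels=ds.labels[train_idx],
    )
    test = ds.replace(
        values=ds.values.iloc[test_idx].reset_index(drop=True),
        labels=ds.labels[test_idx],
    )
    mask = detect_outliers(train, cfg)
    if mask.any():
        train = drop_rows(train, mask, "remove_outliers")
    train = rebalance(train, cfg)
    plan = fit_scalers(train, cfg)
    return apply_scalers(train, plan), apply_scalers(test, plan)


def _clean(ds: TabularDataset, cfg: PreprocessConfig) -> TabularDataset:
    """Row-identity cleaning valid on the full set: duplicates + imputation."""
    ds, _ = remove_duplicates(ds)
    ds, _ = impute_nulls(ds, cfg)
    return ds


def cross_validate(
    ds: TabularDataset, pipeline: PipelineSpec, k: int = 10, seed: int = 0
) -> CVResult:
    """Stratified k-fold evaluation of one combiner."""
    results = compare_combiners(ds, pipeline, k=k, seed=seed, combiners=(pipeline.combiner,))
    return results[pipeline.combiner]


def compare_combiners(
    ds: TabularDataset,
    pipeline: PipelineSpec,
    k: int = 10,
    seed: int = 0,
    combiners: tuple[str, ...] = ("proposed", "classical", "majority"),
) -> dict[str, CVResult]:
    """k-fold CV of several combiners sharing the same base-model fits.

    Per fold the base models are trained once (plus out-of-fold passes for
    the meta layers), so comparing combiners costs little more than
    evaluating one.  ``single:<model_id>`` rows reuse the same fits.
    """
    ds = _clean(ds, pipeline.preprocess)
    assignment = stratified_kfold(ds, k, seed)
    per_fold: dict[str, list[EvaluationMetrics]] = {c: [] for c in combiners}

    needs_meta = any(c in ("proposed", "classical") for c in combiners)
    for fold in range(k):
        te = np.flatnonzero(assignment == fold)
        tr = np.flatnonzero(assignment != fold)
        train, test = _prepare_fold(ds, tr, te, pipeline.preprocess)
        X_test, y_test = test.feature_matrix(), test.labels

        fitted = {n: train_base(train, c) for n, c in pipeline.base_cfgs.items()}
        outputs_test = {n: predict_base(m, X_test) for n, m in fitted.items()}
        model_order = tuple(pipeline.base_cfgs)

        metas: dict[str, LogisticRegression] = {}
        if needs_meta:
            if pipeline.in_sample_meta:
                X_tr = train.feature_matrix()
                oof = {n: predict_base(m, X_tr) for n, m in fitted.items()}
            else:
                oof = _oof_base_outputs(
                    train, pipeline.base_cfgs, pipeline.oof_folds, seed
                )
            mf_tr = build_meta_features(oof, model_order)
            if "proposed" in combiners:
                metas["proposed"] = LogisticRegression(
                    max_iter=2000, random_state=seed
                ).fit(mf_tr.matrix, train.labels)
            if "classical" in combiners:
                metas["classical"] = LogisticRegression(
                    max_iter=2000, random_state=seed
                ).fit(_classes_only(mf_tr), train.labels)

        mf_te = build_meta_features(outputs_test, model_order)
        for comb in combiners:
            if comb == "proposed":
                pos = int(np.flatnonzero(metas[comb].classes_ == 1)[0])
                pred = (metas[comb].predict_proba(mf_te.matrix)[:, pos] >= 0.5).astype(int)
            elif comb == "classical":
                pos = int(np.flatnonzero(metas[comb].classes_ == 1)[0])
                pred = (
                    metas[comb].predict_proba(_classes_only(mf_te))[:, pos] >= 0.5
                ).astype(int)
            elif comb == "majority":
                pred = majority_vote(outputs_test)
            elif comb.startswith("single:"):
                model_id = comb.split(":", 1)[1]
                if model_id not in outputs_test:
                    raise ValueError(f"unknown single model {model_id!r}")
                pred = outputs_test[model_id][0]
            else:
                raise ValueError(f"unknown combiner {comb!r}")
            per_fold[comb].append(metrics(confusion(y_test, pred)))
        logger.info("fold %d/%d evaluated (%d combiners)", fold + 1, k, len(combiners))

    return {
        c: CVResult(
            k=k,
            per_fold=per_fold[c],
            mean_metrics=_mean_metrics(per_fold[c]),
            fold_assignment=assignment,
            seed=seed,
        )
        for c in combiners
    }


# ---------------------------------------------------------------------------
# Report-shaped comparisons
# ---------------------------------------------------------------------------

def compare_frameworks(
    ds: TabularDataset,
    pipeline: PipelineSpec,
    mode: Literal["singles", "combiners"] = "combiners",
    k: int = 10,
    seed: int = 0,
) -> list[dict]:
    """Comparison report rows.

    ``singles``: every base model with and without the preprocessing
    pipeline (two rows per model).  ``combiners``: proposed stacker,
    traditional voting, classical stacking, and the best single model.
    Each row carries accuracy / specificity / sensitivity.
    """
    rows: list[dict] = []
    if mode == "singles":
        raw_pre = PreprocessConfig(
            outlier_method=pipeline.preprocess.outlier_method,
            contamination=0.0,
            rebalance_method="none",
            seed=pipeline.preprocess.seed,
        )
        for condition, pre in (("without_pipeline", raw_pre), ("with_pipeline", pipeline.preprocess)):
            spec = PipelineSpec(
                base_cfgs=pipeline.base_cfgs,
                preprocess=pre,
                oof_folds=pipeline.oof_folds,
            )
            singles = tuple(f"single:{m}" for m in pipeline.base_cfgs)
            res = compare_combiners(ds, spec, k=k, seed=seed, combiners=singles)
            for name, cv in res.items():
                rows.append(
                    {
                        "model": name.split(":", 1)[1],
                        "condition": condition,
                        **{
                            m: cv.mean_metrics[m]
                            for m in ("accuracy", "specificity", "sensitivity")
                        },
                    }
                )
        return rows

    singles = tuple(f"single:{m}" for m in pipeline.base_cfgs)
    res = compare_combiners(
        ds,
        pipeline,
        k=k,
        seed=seed,
        combiners=("proposed", "majority", "classical") + singles,
    )
    best_single = max(
        (c for c in res if c.startswith("single:")),
        key=lambda c: res[c].mean_metrics["accuracy"],
    )
    for label, key in (
        ("proposed_framework", "proposed"),
        ("traditional_voting", "majority"),
        ("classical_stacking", "classical"),
        (f"best_single ({best_single.split(':', 1)[1]})", best_single),
    ):
        cv = res[key]
        rows.append(
            {
                "model": label,
                **{
                    m: cv.mean_metrics[m]
                    for m in ("accuracy", "specificity", "sensitivity")
                },
            }
        )
    return rows
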