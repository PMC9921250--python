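"""First-layer classifiers: lr, svm, xgb, rf, dnn, cnn.

Each model exposes the same contract: train on a preprocessed dataset,
then emit a (class, positive-probability) pair per row where
``class == 1 iff probability >= 0.5``.  Default hyperparameters follow
the reference configuration; all fits are seeded.

The ``xgb`` slot is backed by sklearn gradient-boosted trees and ``dnn``
by sklearn's MLP; ``cnn`` is the in-package numpy 1-D network.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Any, Literal, Mapping

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from ._cnn import ConvNet1D
from .schema import TabularDataset

__all__ = [
    "MODEL_IDS",
    "BaseModelConfig",
    "FittedBaseModel",
    "train_base",
    "predict_base",
    "tune",
    "DegenerateLabelError",
    "FeatureMismatchError",
    "default_config",
]

MODEL_IDS = ("lr", "svm", "xgb", "rf", "dnn", "cnn")


class DegenerateLabelError(ValueError):
    """Training labels contain a single class."""


class FeatureMismatchError(ValueError):
    """Prediction rows do not match the training feature layout."""


# Reference hyperparameters (grid/random-search optima of the source study).
DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "lr": {"alpha": 0.1, "fit_intercept": True, "solver": "sag", "max_iter": 5000},
    "svm": {
        "kernel": "rbf",
        "degree": 3,
        "gamma": "scale",
        "coef0": 0.0,
        "shrinking": True,
    },
    "xgb": {"min_split_loss": 0.001, "max_depth": 5, "n_estimators": 100},
    "rf": {
        "n_trees": 60,
        "max_depth": 4,
        "min_samples_split": 10,
        "min_samples_leaf": 3,
    },
    "dnn": {
        "hidden_layers": 3,
        "hidden_width": 32,
        "activation": "relu",
        "learning_rate": 0.01,
        "solver": "adam",
        "epochs": 200,
        "patience": 20,
    },
    "cnn": {
        "filter_size1": 3,
        "num_filters1": 32,
        "filter_size2": 3,
        "num_filters2": 32,
        "filter_size3": 3,
        "num_filters3": 64,
        "fc_size": 128,
        "learning_rate": 0.01,
        "epochs": 200,
        "batch_size": 32,
        "patience": 20,
    },
}


@dataclass(frozen=True)
class BaseModelConfig:
    model_id: Literal["lr", "svm", "xgb", "rf", "dnn", "cnn"]
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    tuning: Literal["none", "grid", "random"] = "none"
    tuning_grid: Mapping[str, tuple] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        allowed = set(DEFAULT_HYPERPARAMETERS[self.model_id])
        bad = set(self.hyperparameters) - allowed
        if bad:
            raise ValueError(
                f"unknown hyperparameters for {self.model_id}: {sorted(bad)}"
            )

    def resolved(self) -> dict[str, Any]:
        hp = dict(DEFAULT_HYPERPARAMETERS[self.model_id])
        hp.update(self.hyperparameters)
        return hp


def default_config(model_id: str, seed: int = 0, **overrides) -> BaseModelConfig:
    return BaseModelConfig(model_id=model_id, hyperparameters=overrides, seed=seed)


def _build_estimator(cfg: BaseModelConfig):
    hp = cfg.resolved()
    seed = cfg.seed
    if cfg.model_id == "lr":
        return LogisticRegression(
            C=1.0 / hp["alpha"],
            fit_intercept=hp["fit_intercept"],
            solver=hp["solver"],
            max_iter=hp["max_iter"],
            random_state=seed,
        )
    if cfg.model_id == "svm":
        svc = SVC(
            kernel=hp["kernel"],
            degree=hp["degree"],
            gamma=hp["gamma"],
            coef0=hp["coef0"],
            shrinking=hp["shrinking"],
            random_state=seed,
        )
        # Platt-style sigmoid calibration supplies the decision probability
        return CalibratedClassifierCV(svc, method="sigmoid", cv=3, ensemble=False)
    if cfg.model_id == "xgb":
        return GradientBoostingClassifier(
            max_depth=hp["max_depth"],
            min_impurity_decrease=hp["min_split_loss"],
            n_estimators=hp["n_estimators"],
            random_state=seed,
        )
    if cfg.model_id == "rf":
        return RandomForestClassifier(
            n_estimators=hp["n_trees"],
            max_depth=hp["max_depth"],
            min_samples_split=hp["min_samples_split"],
            min_samples_leaf=hp["min_samples_leaf"],
            random_state=seed,
        )
    if cfg.model_id == "dnn":
        return MLPClassifier(
            hidden_layer_sizes=(hp["hidden_width"],) * hp["hidden_layers"],
            activation=hp["activation"],
            solver=hp["solver"],
            learning_rate_init=hp["learning_rate"],
            max_iter=hp["epochs"],
            early_stopping=False,
            n_iter_no_change=hp["patience"],
            random_state=seed,
        )
    if cfg.model_id == "cnn":
        return ConvNet1D(
            filters=(hp["num_filters1"], hp["num_filters2"], hp["num_filters3"]),
            kernel_sizes=(hp["filter_size1"], hp["filter_size2"], hp["filter_size3"]),
            fc_size=hp["fc_size"],
            learning_rate=hp["learning_rate"],
            epochs=hp["epochs"],
            batch_size=hp["batch_size"],
            patience=hp["patience"],
            seed=seed,
        )
    raise ValueError(cfg.model_id)  # pragma: no cover


@dataclass
class FittedBaseModel:
    """Handle around a fitted estimator plus its frozen feature layout."""

    model_id: str
    estimator: Any
    feature_names: tuple[str, ...]
    config: BaseModelConfig

    def predict_proba_positive(self, X: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        classes = getattr(self.estimator, "classes_", np.array([0, 1]))
        pos = int(np.flatnonzero(classes == 1)[0]) if 1 in classes else 1
        return proba[:, pos]


def _as_matrix(rows, feature_names: tuple[str, ...]) -> np.ndarray:
    if isinstance(rows, TabularDataset):
        cols = set(rows.values.columns)
        if not set(feature_names) <= cols:
            raise FeatureMismatchError(
                f"rows lack features: {sorted(set(feature_names) - cols)}"
            )
        return rows.values[list(feature_names)].to_numpy(dtype=float)
    X = np.asarray(rows, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(feature_names):
        raise FeatureMismatchError(
            f"expected {len(feature_names)} feature columns, got {X.shape}"
        )
    return X


def train_base(ds: TabularDataset, cfg: BaseModelConfig) -> FittedBaseModel:
    """Fit one base model on the model-eligible features of ``ds``."""
    feature_names = tuple(ds.feature_names)
    X = ds.feature_matrix()
    y = ds.labels
    if len(np.unique(y)) < 2:
        raise DegenerateLabelError("training labels contain a single class")
    with warnings.catch_warnings():
        # short-epoch network fits legitimately stop before convergence
        warnings.simplefilter("ignore", ConvergenceWarning)
        est = _build_estimator(cfg).fit(X, y)
    return FittedBaseModel(
        model_id=cfg.model_id, estimator=est, feature_names=feature_names, config=cfg
    )


def predict_base(model: FittedBaseModel, rows) -> tuple[np.ndarray, np.ndarray]:
    """(class vector, positive probability vector); class = 1 iff p >= 0.5."""
    X = _as_matrix(rows, model.feature_names)
    p = model.predict_proba_positive(X)
    return (p >= 0.5).astype(int), p


# ---------------------------------------------------------------------------
# Hyperparameter tuning
# ---------------------------------------------------------------------------

def _cv_accuracy(X: np.ndarray, y: np.ndarray, cfg: BaseModelConfig, k: int) -> float:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    accs = []
    for tr, te in skf.split(X, y):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est = _build_estimator(cfg).fit(X[tr], y[tr])
        proba = est.predict_proba(X[te])
        classes = getattr(est, "classes_", np.array([0, 1]))
        pos = int(np.flatnonzero(classes == 1)[0]) if 1 in classes else 1
        pred = (proba[:, pos] >= 0.5).astype(int)
        accs.append(float((pred == y[te]).mean()))
    return float(np.mean(accs))


def tune(
    ds: TabularDataset,
    cfg: BaseModelConfig,
    cv_folds: int = 3,
    random_budget: int = 10,
) -> tuple[BaseModelConfig, list[dict]]:
    """Grid or random search maximizing mean CV accuracy.

    Grid mode exhausts the cartesian product of ``tuning_grid`` in
    deterministic key order; random mode draws ``random_budget`` seeded
    samples from it.  Configurations that fail to fit are recorded in the
    returned error list and skipped.  Ties go to the first candidate in
    iteration order.
    """
    if cfg.tuning == "none":
        raise ValueError("tune() called with tuning='none'")
    if not cfg.tuning_grid:
        raise ValueError("tuning_grid must be non-empty")
    keys = sorted(cfg.tuning_grid)
    combos = list(itertools.product(*(cfg.tuning_grid[k] for k in keys)))
    if cfg.tuning == "random":
        rng = np.random.default_rng(cfg.seed)
        take = min(random_budget, len(combos))
        combos = [combos[i] for i in rng.choice(len(combos), size=take, replace=False)]

    X, y = ds.feature_matrix(), ds.labels
    best_cfg, best_acc = None, -np.inf
    errors: list[dict] = []
    for combo in combos:
        hp = dict(cfg.hyperparameters)
        hp.update(dict(zip(keys, combo)))
        try:
            cand = replace(cfg, hyperparameters=hp, tuning="none", tuning_grid=None)
            acc = _cv_accuracy(X, y, cand, cv_folds)
        except Exception as exc:  # degenerate candidate, e.g. 0 trees
            errors.append({"hyperparameters": dict(zip(keys, combo)), "error": str(exc)})
            continue
        if acc > best_acc:
            best_cfg, best_acc = cand, acc
    if best_cfg is None:
        raise ValueError("no valid configuration in the search space")
    return best_cfg, errors
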