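"""Automated cleaning pipeline: duplicates, nulls, outliers, balance, scaling.

Fixed stage order: duplicate removal → imputation → outlier removal →
label rebalancing → distribution-aware scaling.  Scaler plans are frozen
at fit time (training rows only) and reapplied verbatim to unseen rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN
from sklearn.ensemble import IsolationForest

from .schema import SemanticType, TabularDataset

__all__ = [
    "PreprocessConfig",
    "PreprocessReport",
    "ScalerPlan",
    "ColumnTransform",
    "remove_duplicates",
    "impute_nulls",
    "detect_outliers",
    "rebalance",
    "fit_scalers",
    "apply_scalers",
    "run_pipeline",
    "DegenerateLabelError",
    "UnimputableColumnError",
]


class DegenerateLabelError(ValueError):
    """Operation requires both label classes to be present."""


class UnimputableColumnError(ValueError):
    """A column is entirely missing and cannot be imputed."""


@dataclass
class PreprocessConfig:
    impute_method: Literal["knn", "label_distribution"] = "knn"
    knn_k: int = 5
    outlier_method: Literal["isolation_forest", "zscore", "dbscan"] = "isolation_forest"
    contamination: float = 0.05
    zscore_threshold: float = 3.0
    dbscan_eps: float = 1.5
    dbscan_min_samples: int = 5
    if_n_trees: int = 100
    if_subsample: int = 256
    rebalance_method: Literal["none", "oversample", "undersample"] = "none"
    normality_alpha: float = 0.05
    skew_threshold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.contamination < 0.5:
            raise ValueError("contamination must lie in [0, 0.5)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


@dataclass
class PreprocessReport:
    duplicates_removed: int = 0
    cells_imputed: int = 0
    outliers_removed: int = 0
    column_transforms: dict[str, str] = field(default_factory=dict)
    class_counts_before: tuple[int, int] = (0, 0)
    class_counts_after: tuple[int, int] = (0, 0)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Duplicates
# ---------------------------------------------------------------------------

def remove_duplicates(ds: TabularDataset) -> tuple[TabularDataset, int]:
    """Drop rows whose features AND label match an earlier row."""
    full = ds.values.copy()
    full["__label__"] = ds.labels
    keep = ~full.duplicated(keep="first")
    count = int((~keep).sum())
    if count == 0:
        return ds, 0
    out = ds.replace(
        values=ds.values.loc[keep].reset_index(drop=True),
        labels=ds.labels[keep.to_numpy()],
    )
    out.log("remove_duplicates", removed=count)
    return out, count


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def _fill_value(col: pd.Series, spec_is_numeric: bool):
    if spec_is_numeric:
        return col.mean()
    mode = col.mode()
    return mode.iloc[0] if len(mode) else np.nan


def impute_nulls(
    ds: TabularDataset, cfg: PreprocessConfig
) -> tuple[TabularDataset, int]:
    """Fill every missing cell; returns the imputed dataset and cell count.

    ``knn``: a cell is filled with the mean (numeric) / mode (other) of the
    ``knn_k`` nearest fully-observed rows, by Euclidean distance over the
    numeric features observed in the incomplete row.  ``label_distribution``:
    per-label-class column mean/mode (training-time only — it reads labels).
    """
    n_missing = ds.n_missing()
    if n_missing == 0:
        return ds, 0
    values = ds.values.copy()
    for name in values.columns:
        if values[name].isna().all():
            raise UnimputableColumnError(f"column {name!r} is entirely missing")

    numeric = [c for c in values.columns if ds.schema[c].is_numeric]
    is_num = {c: ds.schema[c].is_numeric for c in values.columns}

    if cfg.impute_method == "label_distribution":
        for cls in (0, 1):
            idx = ds.labels == cls
            sub = values.loc[idx]
            for name in values.columns:
                miss = sub[name].isna()
                if miss.any():
                    observed = sub[name].dropna()
                    fill = (
                        _fill_value(observed, is_num[name])
                        if len(observed)
                        else _fill_value(values[name].dropna(), is_num[name])
                    )
                    values.loc[miss[miss].index, name] = fill
    elif cfg.impute_method == "knn":
        complete = values.dropna()
        if complete.empty:
            raise UnimputableColumnError("no fully observed row available for knn")
        comp_num = complete[numeric].to_numpy(dtype=float)
        incomplete_idx = values.index[values.isna().any(axis=1)]
        for i in incomplete_idx:
            row = values.loc[i]
            observed_num = [c for c in numeric if not pd.isna(row[c])]
            if observed_num:
                cols = [numeric.index(c) for c in observed_num]
                d = np.sqrt(
                    ((comp_num[:, cols] - row[observed_num].to_numpy(dtype=float)) ** 2).sum(axis=1)
                )
            else:
                d = np.zeros(len(complete))
            k = min(cfg.knn_k, len(complete))
            nearest = complete.index[np.argsort(d, kind="stable")[:k]]
            for name in values.columns:
                if pd.isna(row[name]):
                    values.loc[i, name] = _fill_value(
                        complete.loc[nearest, name], is_num[name]
                    )
    else:  # pragma: no cover - config enum
        raise ValueError(f"unknown impute_method {cfg.impute_method!r}")

    out = ds.replace(values=values)
    out.log("impute_nulls", method=cfg.impute_method, cells=n_missing)
    return out, n_missing


# ---------------------------------------------------------------------------
# Outliers
# ---------------------------------------------------------------------------

def detect_outliers(ds: TabularDataset, cfg: PreprocessConfig) -> np.ndarray:
    """Boolean mask over rows; True marks an outlier.

    ``isolation_forest``: isolation-tree ensemble (random sub-samples,
    random split features/values); the ``contamination`` fraction of rows
    with the shortest mean path length — i.e. highest anomaly score — is
    flagged.  ``zscore``: any per-column |z| above ``zscore_threshold``.
    ``dbscan``: density noise points.
    """
    n = ds.n_rows
    if cfg.contamination == 0 and cfg.outlier_method != "zscore":
        return np.zeros(n, dtype=bool)
    X = ds.feature_matrix()

    if cfg.outlier_method == "isolation_forest":
        if n < 8:
            raise ValueError("isolation_forest needs at least 8 rows")
        forest = IsolationForest(
            n_estimators=cfg.if_n_trees,
            max_samples=min(cfg.if_subsample, n),
            random_state=cfg.seed,
        )
        forest.fit(X)
        # score_samples: higher = more normal; flag the k most anomalous
        scores = forest.score_samples(X)
        k = int(np.floor(cfg.contamination * n))
        if k == 0:
            return np.zeros(n, dtype=bool)
        order = np.argsort(scores, kind="stable")
        mask = np.zeros(n, dtype=bool)
        mask[order[:k]] = True
        return mask

    if cfg.outlier_method == "zscore":
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = np.inf
        z = np.abs((X - mu) / sd)
        return (z > cfg.zscore_threshold).any(axis=1)

    if cfg.outlier_method == "dbscan":
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        labels = DBSCAN(eps=cfg.dbscan_eps, min_samples=cfg.dbscan_min_samples).fit(
            (X - X.mean(axis=0)) / sd
        )
        return labels.labels_ == -1

    raise ValueError(f"unknown outlier_method {cfg.outlier_method!r}")


def drop_rows(ds: TabularDataset, mask: np.ndarray, reason: str) -> TabularDataset:
    keep = ~np.asarray(mask, dtype=bool)
    out = ds.replace(
        values=ds.values.loc[keep].reset_index(drop=True), labels=ds.labels[keep]
    )
    out.log(reason, removed=int(mask.sum()))
    return out


# ---------------------------------------------------------------------------
# Rebalancing
# ---------------------------------------------------------------------------

def rebalance(ds: TabularDataset, cfg: PreprocessConfig) -> TabularDataset:
    """Equalize class counts by seeded duplication or seeded dropping."""
    if cfg.rebalance_method == "none":
        return ds
    counts = np.bincount(ds.labels, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise DegenerateLabelError("rebalance requires both classes present")
    if counts[0] == counts[1]:
        return ds
    rng = np.random.default_rng(cfg.seed)
    minority = int(np.argmin(counts))
    majority = 1 - minority
    if cfg.rebalance_method == "oversample":
        need = counts[majority] - counts[minority]
        pool = np.flatnonzero(ds.labels == minority)
        extra = rng.choice(pool, size=need, replace=True)
        values = pd.concat([ds.values, ds.values.iloc[extra]], ignore_index=True)
        labels = np.concatenate([ds.labels, ds.labels[extra]])
    elif cfg.rebalance_method == "undersample":
        pool = np.flatnonzero(ds.labels == majority)
        keep_major = rng.choice(pool, size=counts[minority], replace=False)
        keep = np.sort(
            np.concatenate([np.flatnonzero(ds.labels == minority), keep_major])
        )
        values = ds.values.iloc[keep].reset_index(drop=True)
        labels = ds.labels[keep]
    else:  # pragma: no cover - config enum
        raise ValueError(f"unknown rebalance_method {cfg.rebalance_method!r}")
    out = ds.replace(values=values, labels=labels)
    out.log("rebalance", method=cfg.rebalance_method)
    return out


# ---------------------------------------------------------------------------
# Distribution-aware scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnTransform:
    """Frozen per-column transform decided at fit time.

    kind: 'standardized' | 'max_scaled' | 'log_standardized' | 'constant'
    | 'untouched'.
    """

    kind: str
    mean: float = 0.0
    std: float = 1.0
    max_abs: float = 1.0
    log_shift: float = 0.0


@dataclass(frozen=True)
class ScalerPlan:
    transforms: dict[str, ColumnTransform]

    def record(self) -> dict[str, str]:
        return {name: t.kind for name, t in self.transforms.items()}


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    # D'Agostino-Pearson K^2; needs n >= 20 for a stable test statistic
    if len(x) < 20 or np.ptp(x) == 0:
        return False
    try:
        _, p = stats.normaltest(x)
    except ValueError:
        return False
    return bool(p > alpha)


def fit_scalers(ds: TabularDataset, cfg: PreprocessConfig) -> ScalerPlan:
    """Decide one transform per numeric column from training rows only.

    Normally distributed columns are standardized; among them, columns
    with |skewness| above ``skew_threshold`` are log-transformed first
    (log(1 + x - min) tolerates zeros and negatives).  Non-normal columns
    are scaled by their maximum absolute value.  Binary/categorical
    columns are untouched; constant columns map to all zeros.
    """
    transforms: dict[str, ColumnTransform] = {}
    for name in ds.values.columns:
        spec = ds.schema[name]
        if not spec.is_numeric:
            transforms[name] = ColumnTransform(kind="untouched")
            continue
        x = ds.values[name].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        if len(x) == 0 or np.ptp(x) == 0:
            transforms[name] = ColumnTransform(kind="constant")
            continue
        if _is_normal(x, cfg.normality_alpha):
            if abs(stats.skew(x)) > cfg.skew_threshold:
                shift = 1.0 - x.min()
                logged = np.log(x + shift)
                transforms[name] = ColumnTransform(
                    kind="log_standardized",
                    log_shift=shift,
                    mean=float(logged.mean()),
                    std=float(logged.std() or 1.0),
                )
            else:
                transforms[name] = ColumnTransform(
                    kind="standardized", mean=float(x.mean()), std=float(x.std() or 1.0)
                )
        else:
            transforms[name] = ColumnTransform(
                kind="max_scaled", max_abs=float(np.abs(x).max() or 1.0)
            )
    return ScalerPlan(transforms=transforms)


def apply_scalers(ds: TabularDataset, plan: ScalerPlan) -> TabularDataset:
    """Apply a frozen plan verbatim (valid for training and unseen rows)."""
    values = ds.values.copy()
    for name, t in plan.transforms.items():
        if name not in values.columns or t.kind == "untouched":
            continue
        x = values[name].to_numpy(dtype=float)
        if t.kind == "constant":
            values[name] = np.zeros_like(x)
        elif t.kind == "standardized":
            values[name] = (x - t.mean) / t.std
        elif t.kind == "log_standardized":
            values[name] = (np.log(np.maximum(x + t.log_shift, 1e-12)) - t.mean) / t.std
        elif t.kind == "max_scaled":
            values[name] = x / t.max_abs
        else:  # pragma: no cover
            raise ValueError(f"unknown transform kind {t.kind!r}")
    out = ds.replace(values=values)
    out.log("apply_scalers", plan=plan.record())
    return out


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    ds: TabularDataset, cfg: PreprocessConfig
) -> tuple[TabularDataset, ScalerPlan, PreprocessReport]:
    """duplicates → imputation → outlier removal → rebalance → scaling."""
    report = PreprocessReport()
    counts = np.bincount(ds.labels, minlength=2)
    report.class_counts_before = (int(counts[0]), int(counts[1]))

    ds, report.duplicates_removed = remove_duplicates(ds)
    ds, report.cells_imputed = impute_nulls(ds, cfg)
    mask = detect_outliers(ds, cfg)
    report.outliers_removed = int(mask.sum())
    if mask.any():
        ds = drop_rows(ds, mask, "remove_outliers")
    ds = rebalance(ds, cfg)
    plan = fit_scalers(ds, cfg)
    ds = apply_scalers(ds, plan)

    counts = np.bincount(ds.labels, minlength=2)
    report.class_counts_after = (int(counts[0]), int(counts[1]))
    report.column_transforms = plan.record()
    return ds, plan, report
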