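"""Hybrid voting feature selection.

Six rankers (Pearson, ANOVA F, binned chi-square, recursive elimination,
L1-logistic, decision tree) each produce a full importance ranking; a
voting layer intersects their top-x lists and completes any shortfall by
mean rank (Borda), yielding exactly x features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import RFE, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .schema import TabularDataset

__all__ = [
    "FeatureRanking",
    "SelectionResult",
    "rank_pearson",
    "rank_anova",
    "rank_chi2",
    "rank_rfe",
    "rank_lasso",
    "rank_tree",
    "vote_top_features",
    "select_features",
    "DEFAULT_METHODS",
    "RANKERS",
]

#: The default hybrid set (chi2_binned stays available via config).
DEFAULT_METHODS = ("pearson", "anova", "rfe", "lasso", "tree")


@dataclass(frozen=True)
class FeatureRanking:
    """One method's full ranking: best feature first.

    ``candidates`` preserves the schema column order and is the canonical
    tie-break order for every downstream aggregation step.
    """

    method: str
    ranked_features: tuple[str, ...]
    scores: tuple[float, ...]
    candidates: tuple[str, ...]

    def __post_init__(self) -> None:
        if sorted(self.ranked_features) != sorted(self.candidates):
            raise ValueError("ranked_features must be a permutation of candidates")
        if len(self.scores) != len(self.ranked_features):
            raise ValueError("scores and ranked_features lengths differ")

    def rank_of(self, feature: str) -> int:
        """1-based rank (1 = most important)."""
        return self.ranked_features.index(feature) + 1

    def top(self, x: int) -> list[str]:
        return list(self.ranked_features[:x])


@dataclass(frozen=True)
class SelectionResult:
    selected: tuple[str, ...]
    per_method: tuple[FeatureRanking, ...]
    intersection: frozenset[str]
    fill_in: tuple[tuple[str, float], ...] = ()

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "intersection": sorted(self.intersection),
            "fill_in": [{"feature": f, "mean_rank": r} for f, r in self.fill_in],
            "per_method": [
                {
                    "method": r.method,
                    "ranked_features": list(r.ranked_features),
                    "scores": list(r.scores),
                }
                for r in self.per_method
            ],
        }


def _order(names: list[str], scores: np.ndarray) -> FeatureRanking:
    """Descending-score order; ties broken by schema column position."""
    scores = np.asarray(scores, dtype=float)
    scores = np.nan_to_num(scores, nan=0.0)
    idx = np.argsort(-scores, kind="stable")
    return idx, scores


def _make_ranking(method: str, names: list[str], scores: np.ndarray) -> FeatureRanking:
    idx, scores = _order(names, scores)
    return FeatureRanking(
        method=method,
        ranked_features=tuple(names[i] for i in idx),
        scores=tuple(float(scores[i]) for i in idx),
        candidates=tuple(names),
    )


def _xy(ds: TabularDataset) -> tuple[list[str], np.ndarray, np.ndarray]:
    names = ds.feature_names
    X = ds.feature_matrix()
    if np.isnan(X).any():
        raise ValueError("feature ranking requires an imputed dataset (no missing cells)")
    return names, X, ds.labels


# ---------------------------------------------------------------------------
# Rankers
# ---------------------------------------------------------------------------

def rank_pearson(ds: TabularDataset) -> FeatureRanking:
    """Score = |Pearson correlation(feature, label)|; constants score 0."""
    names, X, y = _xy(ds)
    scores = []
    for j in range(X.shape[1]):
        x = X[:, j]
        if x.std() == 0 or y.std() == 0:
            scores.append(0.0)
        else:
            scores.append(abs(np.corrcoef(x, y)[0, 1]))
    return _make_ranking("pearson", names, np.array(scores))


def rank_anova(ds: TabularDataset) -> FeatureRanking:
    """Score = one-way between/within-class F statistic."""
    names, X, y = _xy(ds)
    with np.errstate(divide="ignore", invalid="ignore"):
        f, _ = f_classif(X, y)
    return _make_ranking("anova", names, np.nan_to_num(f, nan=0.0))


def rank_chi2(ds: TabularDataset, n_bins: int = 5) -> FeatureRanking:
    """Chi-square of (equal-frequency binned feature) × label contingency."""
    names, X, y = _xy(ds)
    scores = []
    for j, name in enumerate(names):
        x = pd.Series(X[:, j])
        if x.nunique() <= 1:
            scores.append(0.0)
            continue
        if x.nunique() > n_bins:
            binned = pd.qcut(x, q=n_bins, duplicates="drop", labels=False)
        else:
            binned = x
        table = pd.crosstab(binned, y)
        if table.shape[0] < 2 or table.shape[1] < 2:
            scores.append(0.0)
            continue
        chi2_stat = stats.chi2_contingency(table.to_numpy())[0]
        scores.append(float(chi2_stat))
    return _make_ranking("chi2_binned", names, np.array(scores))


def rank_rfe(ds: TabularDataset, seed: int = 0) -> FeatureRanking:
    """Recursive elimination under a re-fit linear classifier.

    Score = negative elimination rank, so the last-eliminated (strongest)
    feature scores highest.
    """
    names, X, y = _xy(ds)
    if len(names) == 1:
        return _make_ranking("rfe", names, np.array([1.0]))
    Xs = StandardScaler().fit_transform(X)
    est = LogisticRegression(max_iter=2000, random_state=seed)
    rfe = RFE(est, n_features_to_select=1, step=1).fit(Xs, y)
    return _make_ranking("rfe", names, -rfe.ranking_.astype(float))


_LASSO_C_GRID = (0.01, 0.1, 1.0, 10.0)


def rank_lasso(
    ds: TabularDataset, penalty: float | None = None, seed: int = 0
) -> FeatureRanking:
    """Score = |L1-logistic coefficient| on standardized features.

    With ``penalty=None`` the inverse regularisation strength is chosen by
    5-fold CV over a small grid.
    """
    names, X, y = _xy(ds)
    Xs = StandardScaler().fit_transform(X)

    def _l1(C: float) -> LogisticRegression:
        return LogisticRegression(
            C=C, l1_ratio=1.0, solver="liblinear", random_state=seed, max_iter=2000
        )

    if penalty is None:
        cv = min(5, int(np.bincount(y, minlength=2).min()))
        if cv >= 2:
            skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
            splits = list(skf.split(Xs, y))
            best_C, best_acc = _LASSO_C_GRID[0], -np.inf
            for C in _LASSO_C_GRID:
                acc = np.mean(
                    [
                        (_l1(C).fit(Xs[tr], y[tr]).predict(Xs[te]) == y[te]).mean()
                        for tr, te in splits
                    ]
                )
                if acc > best_acc:
                    best_C, best_acc = C, acc
            model = _l1(best_C).fit(Xs, y)
        else:
            model = _l1(1.0).fit(Xs, y)
    else:
        model = _l1(1.0 / penalty).fit(Xs, y)
    return _make_ranking("lasso", names, np.abs(model.coef_.ravel()))


def rank_tree(ds: TabularDataset, max_depth: int = 5, seed: int = 0) -> FeatureRanking:
    """Score = impurity-decrease importance of a depth-limited tree."""
    names, X, y = _xy(ds)
    tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed).fit(X, y)
    return _make_ranking("tree", names, tree.feature_importances_)


RANKERS = {
    "pearson": rank_pearson,
    "anova": rank_anova,
    "chi2_binned": rank_chi2,
    "rfe": rank_rfe,
    "lasso": rank_lasso,
    "tree": rank_tree,
}


# ---------------------------------------------------------------------------
# Voting
# ---------------------------------------------------------------------------

def vote_top_features(rankings: list[FeatureRanking], x: int) -> SelectionResult:
    """Intersect the top-x lists; complete any shortfall by mean rank.

    The intersection members are ordered by mean rank across all methods;
    when it holds fewer than x features, the best-mean-rank (Borda)
    features outside it fill the remainder, recorded in ``fill_in``.
    Permutation-invariant in the order of ``rankings``.
    """
    if not rankings:
        raise ValueError("rankings must be non-empty")
    candidates = rankings[0].candidates
    for r in rankings:
        if sorted(r.candidates) != sorted(candidates):
            raise ValueError("all rankings must cover the same candidate set")
    if not 1 <= x <= len(candidates):
        raise ValueError(f"x must lie in [1, {len(candidates)}]")

    position = {name: i for i, name in enumerate(candidates)}
    mean_rank = {
        name: float(np.mean([r.rank_of(name) for r in rankings])) for name in candidates
    }
    tops = [set(r.top(x)) for r in rankings]
    intersection = set.intersection(*tops)

    by_rank = sorted(intersection, key=lambda f: (mean_rank[f], position[f]))
    selected = by_rank[:x]
    fill_in: list[tuple[str, float]] = []
    if len(selected) < x:
        rest = sorted(
            (f for f in candidates if f not in intersection),
            key=lambda f: (mean_rank[f], position[f]),
        )
        for f in rest[: x - len(selected)]:
            selected.append(f)
            fill_in.append((f, mean_rank[f]))
    return SelectionResult(
        selected=tuple(selected),
        per_method=tuple(rankings),
        intersection=frozenset(intersection),
        fill_in=tuple(fill_in),
    )


def select_features(
    ds: TabularDataset,
    methods: tuple[str, ...] = DEFAULT_METHODS,
    x: int | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Run the chosen rankers and vote; identifier columns never compete."""
    unknown = set(methods) - set(RANKERS)
    if unknown:
        raise ValueError(f"unknown ranking methods: {sorted(unknown)}")
    if x is None:
        x = len(ds.feature_names)
    rankings = []
    for m in methods:
        fn = RANKERS[m]
        if m in ("rfe", "lasso", "tree"):
            rankings.append(fn(ds, seed=seed))
        else:
            rankings.append(fn(ds))
    return vote_top_features(rankings, x)
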