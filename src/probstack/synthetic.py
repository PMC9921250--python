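"""Seeded synthetic tabular generators.

Labels follow a logistic model over a declared subset of informative
features; everything else is noise drawn independently within schema
ranges.  Nulls, verbatim duplicates, gross outliers and skewed columns
can be injected so every downstream cleaning stage has a true positive
to find.  Identical spec + seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .schema import ColumnSpec, DatasetSchema, SemanticType, TabularDataset

__all__ = ["SyntheticSpec", "SpecError", "generate", "planted_signal_benchmark"]


class SpecError(ValueError):
    """Synthetic spec is internally inconsistent."""


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset."""

    schema: DatasetSchema
    n_rows: int
    informative_features: tuple[str, ...] = ()
    effect_sizes: Mapping[str, float] = field(default_factory=dict)
    intercept: float | None = 0.0
    label_balance: float | None = None
    missing_rate: float = 0.0
    duplicate_count: int = 0
    outlier_count: int = 0
    skewed_features: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        feats = set(self.schema.feature_columns)
        bad = set(self.informative_features) - feats
        if bad:
            raise SpecError(f"informative features not in schema: {sorted(bad)}")
        if self.label_balance is not None and not 0 < self.label_balance < 1:
            raise SpecError("label_balance must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise SpecError("missing_rate must lie in [0, 1)")
        if self.duplicate_count < 0 or self.outlier_count < 0:
            raise SpecError("duplicate/outlier counts must be non-negative")
        if self.duplicate_count + self.outlier_count >= self.n_rows:
            raise SpecError(
                "n_rows too small to honor duplicate_count + outlier_count"
            )


def _draw_column(spec: ColumnSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n values for one column, respecting its declared domain.

    Numeric continuous columns use a truncated normal centred on the range
    midpoint with sd = range/6; ordinal/categorical are uniform over the
    value set; binary is Bernoulli(0.5).
    """
    if spec.semantic_type == SemanticType.BINARY:
        return rng.integers(0, 2, size=n).astype(float)
    if isinstance(spec.allowed_range, frozenset):
        return rng.choice(sorted(spec.allowed_range), size=n).astype(float)
    if spec.allowed_range is not None:
        lo, hi = spec.allowed_range
    else:
        lo, hi = 0.0, 1.0
    mu, sigma = (lo + hi) / 2.0, (hi - lo) / 6.0
    if sigma == 0:
        return np.full(n, mu)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


def _calibrate_intercept(linear: np.ndarray, target: float) -> float:
    """Bisect the intercept so mean sigmoid(linear + c) hits ``target``."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if expit(linear + mid).mean() < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def generate(spec: SyntheticSpec) -> TabularDataset:
    """Materialize a :class:`TabularDataset` from ``spec`` (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    schema = spec.schema
    n_unique = spec.n_rows - spec.duplicate_count
    feature_cols = [c for c in schema.column_names if c != schema.label_column]

    values = pd.DataFrame(
        {
            name: _draw_column(schema[name], n_unique, rng)
            for name in feature_cols
        }
    )

    # Skew injection: replace with a shifted log-normal spanning the range,
    # so a |skewness| test has a genuine positive.
    for name, severity in spec.skewed_features.items():
        col = schema[name]
        z = rng.normal(size=n_unique)
        raw = np.exp(severity * z)
        if col.allowed_range is not None and not isinstance(col.allowed_range, frozenset):
            lo, hi = col.allowed_range
            raw = lo + (hi - lo) * (raw - raw.min()) / (raw.max() - raw.min() + 1e-12)
        values[name] = raw

    # Logistic label model over standardized informative features.
    linear = np.zeros(n_unique)
    for name in spec.informative_features:
        x = values[name].to_numpy()
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        linear += spec.effect_sizes.get(name, 0.0) * z
    if spec.label_balance is not None:
        intercept = _calibrate_intercept(linear, spec.label_balance)
    else:
        intercept = spec.intercept or 0.0
    p = expit(intercept + linear)
    labels = (rng.random(n_unique) < p).astype(int)

    # Duplicates: verbatim copies of seeded-random source rows appended at the end.
    if spec.duplicate_count:
        src = rng.choice(n_unique, size=spec.duplicate_count, replace=True)
        values = pd.concat([values, values.iloc[src]], ignore_index=True)
        labels = np.concatenate([labels, labels[src]])

    # Outliers: displace one numeric feature of chosen rows by >= 6 robust SDs.
    numeric = [c for c in feature_cols if schema[c].is_numeric]
    if spec.outlier_count:
        if not numeric:
            raise SpecError("outlier injection requires a numeric feature")
        # keep injected duplicates verbatim: never displace a duplicate
        # source or copy
        dup_src = set(src.tolist()) if spec.duplicate_count else set()
        eligible = np.array(sorted(set(range(n_unique)) - dup_src))
        if len(eligible) < spec.outlier_count:
            raise SpecError("n_rows too small to honor outlier_count")
        rows = rng.choice(eligible, size=spec.outlier_count, replace=False)
        for r in rows:
            name = numeric[rng.integers(len(numeric))]
            x = values[name].to_numpy()
            mad = stats.median_abs_deviation(x, scale="normal")
            robust_sd = mad if mad > 0 else (x.std() or 1.0)
            values.loc[r, name] = np.median(x) + 10.0 * robust_sd

    # Missing cells (never in the label).
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = values.mask(mask)

    ds = TabularDataset(schema=schema, values=values, labels=labels)
    ds.log(
        "synthetic_generate",
        seed=spec.seed,
        n_rows=spec.n_rows,
        intercept=float(intercept),
        informative=list(spec.informative_features),
    )
    return ds


def _uniform_feature_schema(n_features: int, label: str = "target") -> DatasetSchema:
    cols = [
        ColumnSpec(f"f{i}", SemanticType.NUMERIC_CONTINUOUS, (-4.0, 4.0))
        for i in range(n_features)
    ]
    cols.append(ColumnSpec(label, SemanticType.BINARY))
    return DatasetSchema(columns=tuple(cols), label_column=label)


def planted_signal_benchmark(
    n_informative: int,
    n_noise: int,
    n_rows: int,
    seed: int,
    base_effect: float = 1.5,
    decay: float = 0.85,
) -> tuple[TabularDataset, set[str]]:
    """Dataset with a known informative feature set and descending effects.

    Features ``f0..f(k-1)`` carry logistic effects ``base_effect * decay**i``
    (so the expected importance ordering is known); the remaining
    ``n_noise`` features are label-independent noise.  Returns the dataset
    and the ground-truth informative set.
    """
    if n_informative < 1:
        raise SpecError("n_informative must be >= 1")
    total = n_informative + n_noise
    schema = _uniform_feature_schema(total)
    informative = tuple(f"f{i}" for i in range(n_informative))
    effects = {
        name: base_effect * decay**i for i, name in enumerate(informative)
    }
    spec = SyntheticSpec(
        schema=schema,
        n_rows=n_rows,
        informative_features=informative,
        effect_sizes=effects,
        intercept=0.0,
        seed=seed,
    )
    return generate(spec), set(informative)
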