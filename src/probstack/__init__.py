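"""probstack: schema-agnostic binary-classification toolkit.

Hybrid voting feature selection, an automated preprocessing pipeline,
and a two-layer stacking classifier whose meta layer consumes both the
class decisions and the decision probabilities of heterogeneous base
models.
"""

from .schema import (
    ColumnSpec,
    DatasetSchema,
    TabularDataset,
    chd_schema,
    load_dataset,
    load_schema_file,
    uci_schema,
    write_dataset,
)
from .synthetic import SyntheticSpec, generate, planted_signal_benchmark
from .preprocess import (
    PreprocessConfig,
    PreprocessReport,
    apply_scalers,
    detect_outliers,
    fit_scalers,
    impute_nulls,
    rebalance,
    remove_duplicates,
    run_pipeline,
)
from .selection import (
    DEFAULT_METHODS,
    FeatureRanking,
    SelectionResult,
    select_features,
    vote_top_features,
)
from .models import BaseModelConfig, default_config, predict_base, train_base, tune
from .stacking import (
    MetaFeatures,
    StackedModel,
    build_meta_features,
    fit_classical_stack,
    fit_stacked,
    majority_vote,
    predict_stacked,
)
from .evaluate import (
    ConfusionCounts,
    CVResult,
    EvaluationMetrics,
    PipelineSpec,
    compare_combiners,
    compare_frameworks,
    confusion,
    cross_validate,
    metrics,
    stratified_kfold,
)

__version__ = "0.1.0"

__all__ = [
    "ColumnSpec",
    "DatasetSchema",
    "TabularDataset",
    "uci_schema",
    "chd_schema",
    "load_dataset",
    "write_dataset",
    "load_schema_file",
    "SyntheticSpec",
    "generate",
    "planted_signal_benchmark",
    "PreprocessConfig",
    "PreprocessReport",
    "remove_duplicates",
    "impute_nulls",
    "detect_outliers",
    "rebalance",
    "fit_scalers",
    "apply_scalers",
    "run_pipeline",
    "DEFAULT_METHODS",
    "FeatureRanking",
    "SelectionResult",
    "select_features",
    "vote_top_features",
    "BaseModelConfig",
    "default_config",
    "train_base",
    "predict_base",
    "tune",
    "MetaFeatures",
    "StackedModel",
    "build_meta_features",
    "fit_stacked",
    "fit_classical_stack",
    "predict_stacked",
    "majority_vote",
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
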