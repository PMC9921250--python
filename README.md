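# probstack

Schema-agnostic binary-classification toolkit for tabular clinical data:

- **Hybrid voting feature selection** — five rankers (Pearson, ANOVA F,
  recursive elimination, L1-logistic, decision tree; binned chi-square
  available) vote on their top-*x* lists; the intersection is completed
  by mean rank (Borda) to exactly *x* features.
- **Automated preprocessing pipeline** — duplicate removal, KNN or
  per-class imputation, isolation-forest / z-score / DBSCAN outlier
  removal, over/undersampling rebalance, and distribution-aware scaling
  (normality test → standardize; skewed-normal → log then standardize;
  non-normal → max-scale).
- **Probability-augmented stacking** — six heterogeneous base models
  (logistic regression, calibrated RBF-SVM, gradient-boosted trees,
  random forest, MLP, and an in-package numpy 1-D CNN) feed a logistic
  meta layer with both their class decisions *and* their decision
  probabilities (2M meta-features). Meta-features for training rows are
  produced out-of-fold, so no base model scores a row it was trained on.
  Baseline combiners (majority voting, classes-only classical stacking)
  are built in for comparison.
- **Evaluation** — confusion-based accuracy / specificity / sensitivity /
  precision / F1, stratified k-fold CV with fold-local preprocessing,
  and comparison reports for single models and combiners.
- **Synthetic data** — seeded generators with planted informative
  features, injectable nulls / duplicates / outliers / skew, and
  intercept calibration to a target label balance, so the whole pipeline
  is testable without any external download.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (metric and
voting oracles, feature recovery, stacking direction, preprocessing
contracts, pipeline determinism). The stacking-direction check runs
10-fold CV over 20 seeds and takes a few minutes on one CPU.

## CLI

```bash
# seeded synthetic CSV (UCI-like layout) + ground-truth sidecar
probstack generate --schema uci --n-rows 500 --seed 1 --out data.csv

# hybrid voting feature selection
probstack select data.csv --schema uci --x 5 --report selection.json

# cross-validated metrics / comparison report / full run
probstack evaluate data.csv --config config.yaml
probstack compare data.csv --config config.yaml --table4 --out report.json
probstack run data.csv --config config.yaml

# fit and persist the stacked ensemble, then predict
probstack train data.csv --config config.yaml --out model.joblib
probstack predict data.csv --bundle model.joblib --out preds.csv
```

A config file looks like:

```yaml
schema: uci            # builtin name (uci, chd) or a YAML/JSON schema file
preprocess:
  impute_method: knn
  outlier_method: isolation_forest
  contamination: 0.05
  rebalance_method: none
  seed: 0
selection: {x: 5}      # omit to use all non-identifier features
base_models:
  - {model_id: lr}
  - {model_id: rf}
  - {model_id: cnn, hyperparameters: {epochs: 60}}
stacking: {oof_folds: 5, combiner: proposed}   # proposed | classical | majority | single:<id>
evaluation: {k: 10, seed: 0}
output_dir: runs/demo
```

Given real UCI/CHD CSV exports, `probstack run --config ...` executes the
full pipeline end to end on them; no external download is performed or
required by the test suite.

## Layout

```
src/probstack/
  schema.py      column specs, dataset container, CSV I/O, reference schemas
  synthetic.py   seeded generators, planted-signal benchmark
  preprocess.py  duplicates, imputation, outliers, rebalance, scaling
  selection.py   six rankers + voting layer
  models.py      the six base classifiers and tuning
  _cnn.py        numpy 1-D convolutional network
  stacking.py    probability-augmented stacker + baseline combiners
  evaluate.py    metrics, stratified k-fold CV, comparison reports
  cli.py         click command group
```
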