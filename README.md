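# bbbkit

A toolkit for modelling blood–brain-barrier (BBB) permeability of small
molecules:

- **Feature selection** by a differential Shannon-entropy score (combined
  class histogram entropy minus the mean of per-class entropies; log base 2,
  range [0, 1], invariant to class imbalance), followed by a Pearson-
  correlation redundancy filter (|PCC| ≥ 0.8), a 0.1 score threshold, and a
  cap of 50 descriptors per set.
- **Structural keys**: 2D descriptors whose missing value signals substructure
  absence, retained when per-class absence frequencies differ by ≥ 0.2
  (MIN/MAX electrotopological-state twins deduplicated to the MAX member;
  sum-of-E-state descriptors excluded).
- **Property fingerprints**: per-descriptor thermometer bit fields (1, 4 or
  8 bits) over training-set boundaries `bound_i = val_min + i · val_range / bits`,
  with structural-key presence bits in the leading positions.
- **Dataset splitting** by a greedy max–min (Kennard-Stone style) selector
  over Euclidean, Mahalanobis or 1 − Tanimoto distances, optionally with the
  class label as an extra coordinate.
- **Classifiers**: random forest and SVM (RBF / polynomial) with the class
  weighting `n_samples / (n_classes · class_count)`, exhaustive grid search
  under stratified 10-fold CV, and a Mahalanobis applicability-domain
  distance reported with every prediction.
- **Evaluation**: sensitivity, specificity, accuracy, balanced accuracy,
  precision, F1, MCC, Cohen's kappa and ROC-AUC, with explicit
  undefined-with-reason handling of zero margins.
- **Synthetic data**: a seeded generator of two-class descriptor tables with
  planted informative/noise/correlated/structural-key descriptors and a
  ground-truth manifest, so the entire pipeline is testable offline.

## CLI

Every pipeline stage is a subcommand; `run` chains them from a JSON config:

```bash
# generate a synthetic descriptor table + labels + manifest
bbbkit simulate --n-active 300 --n-inactive 100 --separation 3 --seed 1 \
    --out-prefix scratch/syn

# standalone stages
bbbkit standardize --input compounds.csv --out clean.csv --log removals.csv
bbbkit select-features --descriptors desc.csv --labels labels.csv --out sel.json
bbbkit fit-fingerprint --descriptors train.csv --selection sel.json --bits 8 \
    --schema schema.json
bbbkit encode --descriptors desc.csv --schema schema.json --out fp.csv
bbbkit split --descriptors fp.csv --metric mahalanobis --train-fraction 0.8 \
    --train-out train_ids.csv --test-out test_ids.csv
bbbkit train --fingerprints fp.csv --labels labels.csv --family random_forest \
    --cv 10 --seed 1 --model-out model.joblib
bbbkit predict --model model.joblib --fingerprints fp.csv --out pred.csv
bbbkit evaluate --predictions pred.csv --truth labels.csv --out metrics.json

# full pipeline from a config file
bbbkit run --config config.json --out runs/demo
```

A minimal `config.json` for a synthetic end-to-end run:

```json
{
  "seed": 1, "bits": 8, "metric": "euclidean", "train_fraction": 0.8,
  "family": "random_forest",
  "grid": [{"n_estimators": 100, "max_depth": 20}],
  "cv_k": 5,
  "synthetic": {"n_active": 300, "n_inactive": 100, "separation": 3.0}
}
```

File-based inputs use `"descriptors"` / `"labels"` paths instead of the
`"synthetic"` block. Labels CSVs have columns `id,label`; compound CSVs have
`id,smiles,logbb,label` (labels derived from logBB ≥ −1 when absent).

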