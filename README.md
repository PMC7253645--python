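# cardiochain

Multi-label prediction of drug-induced cardiotoxicity from dual
transcriptomic + molecular features, built around:

- a **classifier chain with nested stacking** over seven ordered adverse-event
  labels (a leading vascular label that seeds the chain plus six cardiac
  disorder groups), with an independent-binary-classifier baseline behind the
  same pluggable base-learner contract (elastic-net logistic regression,
  random forest, gradient boosting);
- **leave-drug-out (grouped) cross-validation** vs random cross-validation,
  with SMOTE class-imbalance correction applied strictly inside training
  folds, and Latin-hypercube hyperparameter tuning toward mean Matthews
  correlation;
- **dual feature selection** for transcriptional features: greedy best-first
  CFS (correlation-based merit with redundancy penalty) and a Boruta-style
  shadow-feature wrapper;
- **molecular features from SMILES**: seven descriptors (MW, XLogP, apol,
  TopoPSA, tpsaEfficiency, ALogP, AMR) and the 79-bit E-state atom-type
  fingerprint, via RDKit;
- **Cohen's-Kappa association analysis** (with independence-null Z-test) for
  label co-occurrence, feature-set similarity, and relationship preservation
  between predicted and true label structures;
- a **synthetic data generator** (Gaussian-copula correlated imbalanced
  labels, replicated expression profiles with label-informative genes and a
  drug-specific random effect, label-informative fingerprint bits) with full
  ground truth for recovery and leakage experiments.

## CLI

The `cardiochain` entry point covers the whole synthetic-to-report path:

```bash
cardiochain simulate --n-drugs 200 --n-genes 100 --seed 1 --out-dir data/
cardiochain curate --drugs data/drugs.tsv --effects data/effects.tsv \
    --hierarchy data/hierarchy.tsv --expression data/expression.tsv \
    --test-fraction 0.2 --seed 1 --out-dir curated/
cardiochain featurize --drugs data/drugs.tsv --out molecular.tsv
cardiochain select-features --features curated/collapsed.tsv \
    --labels curated/labels.tsv --method both --out selected.tsv
cardiochain train --features features.tsv --labels curated/labels.tsv \
    --model chain --learner random_forest --out model.joblib
cardiochain predict --model model.joblib --features features.tsv --out pred.tsv
cardiochain evaluate --model model.joblib --features features.tsv \
    --labels curated/labels.tsv --out-dir report/
cardiochain crossval --features features.tsv --labels curated/labels.tsv \
    --model chain --out-dir cv/
```

All tables are UTF-8 tab-separated with a mandatory header row. Pipeline
configuration is YAML (`seed`, `cv`, `smote`, `tuning`, `chain`,
`base_learner` sections); every random behaviour derives from the seed.

## Package layout

```
src/cardiochain/
  datamodel.py   domain types, configuration, shared invariants
  io.py          TSV readers/writers, YAML config loader
  synth.py       synthetic dataset generator with ground truth
  curation.py    labeling, safe controls, sample collapsing, target split
  features.py    descriptors, E-state fingerprint, CFS, Boruta-style wrapper
  chain.py       classifier chain with nested stacking + binary baseline
  evaluation.py  metrics (MCC/AUC/F1/Kappa), CV plans, SMOTE, LHS tuning
  pipeline.py    cross-validated runs and MCC-objective tuning
  studies.py     canned simulation studies (chain benefit, CV inflation, ...)
  cli.py         click-based command line
```
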