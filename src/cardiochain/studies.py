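"""Reproducible simulation studies exercising the full pipeline.

These are the canned experiments behind the qualitative claims the package
is built around: the chain-vs-binary benefit on dependent labels, the
validation inflation of random (non-grouped) cross-validation, and
feature-selection recovery of planted signal genes.  Each study is a pure
function of its seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chain import BaseLearnerSpec, fit_binary_set, fit_chain, predict_binary_set, predict_chain
from .curation import collapse_samples, join_molecular, split_by_targets
from .datamodel import (
    CARDIAC_GROUPS,
    ChainConfig,
    CVConfig,
    FeatureMatrix,
    LabelMatrix,
    PipelineConfig,
    SmoteConfig,
    TuningConfig,
)
from .evaluation import evaluate, kappa_frobenius_distance, relationship_preservation
from .features import cfs_select, wrapper_select
from .pipeline import cross_validate, tune_learner
from .synth import GeneratorConfig, generate_dataset

log = logging.getLogger(__name__)


def relative_change_percent(baseline: float, value: float) -> float:
    """Percentage change from baseline to value."""
    return 100.0 * (value - baseline) / baseline


def equicorrelation(rho: float) -> np.ndarray:
    corr = np.full((7, 7), rho)
    np.fill_diagonal(corr, 1.0)
    return corr


# --------------------------------------------------------------------------
# Chain benefit + relationship preservation
# --------------------------------------------------------------------------

@dataclass
class ChainBenefitResult:
    chain_test_auc: float
    binary_test_auc: float
    chain_kappa_distance: float
    binary_kappa_distance: float
    n_train_rows: int
    n_test_rows: int


def chain_benefit_config(seed: int) -> GeneratorConfig:
    """High label dependency (rho = 0.8), half-shared informative genes,
    300 drugs x 6 replicate profiles."""
    return GeneratorConfig(
        n_drugs=300,
        label_corr=equicorrelation(0.8),
        prevalence=(0.55, 0.45, 0.35, 0.25, 0.15, 0.15, 0.15),
        n_genes=150,
        informative_genes_per_label=4,
        shared_informative_fraction=0.5,
        gene_effect_size=0.35,
        drug_random_effect_sd=0.8,
        noise_sd=1.0,
        cell_lines=("A", "B"),
        times_h=(6.0, 12.0, 24.0),
        concentrations_per_drug=1,
        fp_bit_logodds=0.5,
        seed=seed,
    )


def run_chain_benefit(seed: int, n_estimators: int = 80) -> ChainBenefitResult:
    bundle = generate_dataset(chain_benefit_config(seed))
    features = join_molecular(collapse_samples(bundle.profiles), bundle.molecular)
    plan = split_by_targets(bundle.drugs, bundle.labels, test_fraction=0.2, seed=seed)
    drug_ids = features.row_meta["drug_id"].to_numpy()
    train = features.select_rows(np.isin(drug_ids, sorted(plan.train_drugs)))
    test = features.select_rows(np.isin(drug_ids, sorted(plan.test_drugs)))
    config = replace(
        PipelineConfig(seed=seed),
        chain=ChainConfig(stacking_inner_folds=3, downstream_signal="hard_label"),
        smote=SmoteConfig(enabled=True, target_ratio=1.0, k_neighbors=5),
    ).validate()
    spec = BaseLearnerSpec("random_forest", {"n_estimators": n_estimators})
    chain = fit_chain(train, bundle.labels, spec, config)
    binary = fit_binary_set(train, bundle.labels, spec, config)
    chain_pred = predict_chain(chain, test)
    binary_pred = predict_binary_set(binary, test)
    chain_report = evaluate(chain_pred, bundle.labels, context="chain/test")
    binary_report = evaluate(binary_pred, bundle.labels, context="binary/test")
    ck_pred, ck_true, _ = relationship_preservation(chain_pred, bundle.labels)
    bk_pred, bk_true, _ = relationship_preservation(binary_pred, bundle.labels)
    return ChainBenefitResult(
        chain_test_auc=chain_report.aggregate["mean_auc"],
        binary_test_auc=binary_report.aggregate["mean_auc"],
        chain_kappa_distance=kappa_frobenius_distance(ck_pred, ck_true),
        binary_kappa_distance=kappa_frobenius_distance(bk_pred, bk_true),
        n_train_rows=len(train.row_meta),
        n_test_rows=len(test.row_meta),
    )


# --------------------------------------------------------------------------
# CV inflation (random vs leave-drug-out)
# --------------------------------------------------------------------------

@dataclass
class CVInflationResult:
    validation_auc_random: float
    validation_auc_ldo: float
    test_auc_random: float
    test_auc_ldo: float


def cv_inflation_config(seed: int) -> GeneratorConfig:
    """Drug random effect 1.5x the noise SD: strong drug-identity signature."""
    return GeneratorConfig(
        n_drugs=150,
        label_corr=equicorrelation(0.3),
        prevalence=(0.5, 0.45, 0.4, 0.35, 0.3, 0.3, 0.3),
        n_genes=80,
        informative_genes_per_label=6,
        gene_effect_size=0.8,
        drug_random_effect_sd=1.5,
        noise_sd=1.0,
        cell_lines=("A", "B"),
        times_h=(6.0, 24.0),
        concentrations_per_drug=1,
        seed=seed,
    )


def run_cv_inflation(seed: int, n_estimators: int = 60) -> CVInflationResult:
    """Tune + validate a binary random-forest set under both CV strategies,
    then score the strategy-selected models on unseen drugs."""
    bundle = generate_dataset(cv_inflation_config(seed))
    features = join_molecular(collapse_samples(bundle.profiles), bundle.molecular)
    plan = split_by_targets(bundle.drugs, bundle.labels, test_fraction=0.2, seed=seed)
    drug_ids = features.row_meta["drug_id"].to_numpy()
    train = features.select_rows(np.isin(drug_ids, sorted(plan.train_drugs)))
    test = features.select_rows(np.isin(drug_ids, sorted(plan.test_drugs)))
    spec = BaseLearnerSpec("random_forest", {"n_estimators": n_estimators})
    out = {}
    for strategy in ("random", "leave_drug_out"):
        config = replace(
            PipelineConfig(seed=seed),
            cv=CVConfig(k_folds=3, strategy=strategy),
            smote=SmoteConfig(enabled=False),
            tuning=TuningConfig(n_lhs_samples=3),
        ).validate()
        best, _ = tune_learner(
            train, bundle.labels, spec, config, model="binary",
            space={"max_depth": (3, 14)},
        )
        _, val_report = cross_validate(train, bundle.labels, best, config, model="binary")
        final = fit_binary_set(train, bundle.labels, best, config)
        test_report = evaluate(
            predict_binary_set(final, test), bundle.labels, context=f"binary/{strategy}/test"
        )
        out[strategy] = (
            val_report.aggregate["mean_auc"],
            test_report.aggregate["mean_auc"],
        )
    return CVInflationResult(
        validation_auc_random=out["random"][0],
        validation_auc_ldo=out["leave_drug_out"][0],
        test_auc_random=out["random"][1],
        test_auc_ldo=out["leave_drug_out"][1],
    )


# --------------------------------------------------------------------------
# Feature-selection recovery
# --------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    planted: list[str]
    wrapper_found: list[str]
    cfs_found: list[str]
    wrapper_fraction: float
    cfs_fraction: float


def planted_gene_matrix(
    seed: int,
    n_drugs: int = 400,
    n_noise_genes: int = 200,
    n_planted: int = 10,
    effect: float = 2.0,
) -> tuple[FeatureMatrix, np.ndarray, list[str]]:
    """Planted-signal design: ``n_planted`` genes shifted by ``effect`` SD in
    positive drugs among pure-noise genes, one profile per drug."""
    rng = np.random.default_rng(seed)
    n_genes = n_noise_genes + n_planted
    y = rng.integers(0, 2, n_drugs)
    x = rng.normal(size=(n_drugs, n_genes))
    planted_idx = rng.choice(n_genes, size=n_planted, replace=False)
    x[:, planted_idx] += effect * y[:, None]
    names = [f"G{i:04d}" for i in range(n_genes)]
    meta = pd.DataFrame(
        {
            "drug_id": [f"D{i:04d}" for i in range(n_drugs)],
            "cell_line": "A",
            "time_h": 6.0,
            "concentration": 1.0,
        }
    )
    matrix = FeatureMatrix(meta, names, x, {"transcriptional": list(names)})
    return matrix, y, [names[i] for i in planted_idx]


def run_recovery(seed: int, n_iterations: int = 15) -> RecoveryResult:
    matrix, y, planted = planted_gene_matrix(seed)
    wrapper = wrapper_select(matrix, y, n_iterations=n_iterations, seed=seed)
    cfs = cfs_select(matrix, y)
    planted_set = set(planted)
    return RecoveryResult(
        planted=planted,
        wrapper_found=sorted(planted_set & set(wrapper.genes)),
        cfs_found=sorted(planted_set & set(cfs.genes)),
        wrapper_fraction=len(planted_set & set(wrapper.genes)) / len(planted),
        cfs_fraction=len(planted_set & set(cfs.genes)) / len(planted),
    )


def run_noise_recovery(seed: int, n_iterations: int = 12) -> int:
    """Number of genes the wrapper confirms on a pure-noise design."""
    rng = np.random.default_rng(seed)
    n_drugs, n_genes = 400, 200
    y = rng.integers(0, 2, n_drugs)
    x = rng.normal(size=(n_drugs, n_genes))
    names = [f"G{i:04d}" for i in range(n_genes)]
    meta = pd.DataFrame(
        {
            "drug_id": [f"D{i:04d}" for i in range(n_drugs)],
            "cell_line": "A",
            "time_h": 6.0,
            "concentration": 1.0,
        }
    )
    matrix = FeatureMatrix(meta, names, x, {"transcriptional": list(names)})
    selected = wrapper_select(matrix, y, n_iterations=n_iterations, seed=seed)
    return len(selected.genes)
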