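"""Orchestration: cross-validated training runs pooling out-of-fold
predictions, and hyperparameter tuning toward mean cardiac MCC."""
from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .chain import (
    BaseLearnerSpec,
    PredictionSet,
    fit_binary_set,
    fit_chain,
    predict_binary_set,
    predict_chain,
)
from .datamodel import CARDIAC_GROUPS, FeatureMatrix, LabelMatrix, PipelineConfig
from .evaluation import (
    ConfusionCounts,
    CVPlan,
    make_folds,
    matthews_cc,
    MetricsReport,
    evaluate,
    lhs_tune,
)

log = logging.getLogger(__name__)


def cross_validate(
    features: FeatureMatrix,
    labels: LabelMatrix,
    spec: BaseLearnerSpec,
    config: PipelineConfig,
    model: str = "chain",
    plan: CVPlan | None = None,
) -> tuple[PredictionSet, MetricsReport]:
    """Fit per fold, score the held-out rows, pool out-of-fold predictions."""
    if plan is None:
        plan = make_folds(
            features.row_meta, config.cv.k_folds, config.cv.strategy, config.seed
        )
    n = len(features.row_meta)
    pooled: np.ndarray | None = None
    label_order: list[str] | None = None
    for tr, va in plan.folds:
        tr_features = features.select_rows(np.asarray(tr, dtype=int))
        va_features = features.select_rows(np.asarray(va, dtype=int))
        if model == "chain":
            fitted = fit_chain(tr_features, labels, spec, config)
            predictions = predict_chain(fitted, va_features)
        elif model == "binary":
            fitted = fit_binary_set(tr_features, labels, spec, config)
            predictions = predict_binary_set(fitted, va_features)
        else:
            raise ValueError(f"unknown model kind {model!r}")
        if pooled is None:
            label_order = predictions.labels
            pooled = np.zeros((n, len(label_order)))
        pooled[list(va)] = predictions.probabilities
    prediction_set = PredictionSet(
        row_meta=features.row_meta.copy(),
        labels=list(label_order),
        probabilities=pooled,
    )
    report = evaluate(prediction_set, labels, context=f"{model}/{plan.strategy} pooled OOF")
    return prediction_set, report


def mean_cardiac_mcc(predictions: PredictionSet, labels: LabelMatrix) -> float:
    """Tuning objective: mean MCC over the six cardiac labels (vascular excluded)."""
    truth = labels.align_rows(predictions.row_meta["drug_id"].tolist())
    values = []
    for j, name in enumerate(predictions.labels):
        if name not in CARDIAC_GROUPS:
            continue
        y = truth[:, labels.labels.index(name)]
        hard = (predictions.probabilities[:, j] >= predictions.threshold).astype(int)
        values.append(matthews_cc(ConfusionCounts.from_vectors(y, hard)))
    return float(np.mean(values))


def tune_learner(
    features: FeatureMatrix,
    labels: LabelMatrix,
    spec: BaseLearnerSpec,
    config: PipelineConfig,
    model: str = "chain",
    space: dict[str, tuple[float, float]] | None = None,
) -> tuple[BaseLearnerSpec, list]:
    """Latin-hypercube search over the learner's declared ranges, maximizing
    cross-validated mean cardiac MCC."""
    space = space or spec.ranges()

    def objective(params: dict[str, float]) -> float:
        candidate = BaseLearnerSpec(spec.family, {**dict(spec.hyperparameters), **params})
        _, report = cross_validate(features, labels, candidate, config, model=model)
        return report.aggregate["mean_mcc"]

    best_params, history = lhs_tune(
        space, config.tuning.n_lhs_samples, objective, config.seed
    )
    best = BaseLearnerSpec(spec.family, {**dict(spec.hyperparameters), **best_params})
    log.info("tuning selected %s", best_params)
    return best, history
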