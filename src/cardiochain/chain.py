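"""Classifier chain with nested stacking and the independent-binary baseline.

Position 1 of the chain is always the vascular label; positions 2-7 are the
six cardiac groups ordered by descending positive-drug count.  The model at
position L consumes the F base feature columns plus L-1 upstream label
signals.  During training those signals are OUT-OF-FOLD predictions from an
internal leave-drug-out split (nested stacking): no downstream model ever
sees in-sample fitted values or true labels as inputs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .datamodel import (
    ConfigValidationError,
    FeatureMatrix,
    LABEL_GROUPS,
    LabelMatrix,
    PipelineConfig,
    SchemaError,
)
from .evaluation import CVPlan, make_folds, smote_oversample

log = logging.getLogger(__name__)

SIGNAL_PREFIX = "chain_signal"


@dataclass(frozen=True)
class BaseLearnerSpec:
    """Pluggable base-learner contract: fit(X, y) / predict_proba -> [0, 1]."""

    family: str = "random_forest"
    hyperparameters: Mapping[str, float] = field(default_factory=dict)

    RANGES = {
        "penalized_logistic": {"C": (0.01, 10.0), "l1_ratio": (0.0, 1.0)},
        "random_forest": {
            "n_estimators": (10, 300),
            "max_depth": (2, 16),
            "min_samples_leaf": (1, 8),
        },
        "gradient_boosting": {
            "n_estimators": (10, 300),
            "learning_rate": (0.01, 0.3),
            "max_depth": (1, 6),
        },
    }

    def __post_init__(self) -> None:
        if self.family not in self.RANGES:
            raise ConfigValidationError(f"unknown base-learner family {self.family!r}")
        for name, value in self.hyperparameters.items():
            if name in self.RANGES[self.family]:
                lo, hi = self.RANGES[self.family][name]
                if not lo <= value <= hi:
                    raise ConfigValidationError(
                        f"{self.family}.{name}={value} outside declared range [{lo}, {hi}]"
                    )

    def ranges(self) -> dict[str, tuple[float, float]]:
        return dict(self.RANGES[self.family])

    def build(self, seed: int) -> BaseEstimator:
        hp = dict(self.hyperparameters)
        if self.family == "penalized_logistic":
            # elastic net: saga solver with a mixed l1_ratio
            model = LogisticRegression(
                solver="saga",
                C=float(hp.get("C", 1.0)),
                l1_ratio=float(hp.get("l1_ratio", 0.5)),
                max_iter=5000,
                random_state=seed,
            )
            return Pipeline([("scale", StandardScaler()), ("model", model)])
        if self.family == "random_forest":
            return RandomForestClassifier(
                n_estimators=int(hp.get("n_estimators", 100)),
                max_depth=(int(hp["max_depth"]) if "max_depth" in hp else None),
                min_samples_leaf=int(hp.get("min_samples_leaf", 1)),
                random_state=seed,
                n_jobs=1,
            )
        return GradientBoostingClassifier(
            n_estimators=int(hp.get("n_estimators", 100)),
            learning_rate=float(hp.get("learning_rate", 0.1)),
            max_depth=int(hp.get("max_depth", 3)),
            random_state=seed,
        )


class ConstantScorer:
    """Fallback for single-class training labels: emits the training prevalence."""

    def __init__(self, prevalence: float):
        self.prevalence = float(prevalence)

    def fit(self, x, y):  # pragma: no cover - interface symmetry
        return self

    def predict_proba(self, x):
        p = np.full(len(x), self.prevalence)
        return np.column_stack([1 - p, p])


def _positive_proba(model, x: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(x)
    if isinstance(model, ConstantScorer):
        return proba[:, 1]
    classes = list(getattr(model, "classes_", [0, 1]))
    if hasattr(model, "steps"):  # Pipeline
        classes = list(model.steps[-1][1].classes_)
    if 1 not in classes:
        return np.zeros(len(x))
    return proba[:, classes.index(1)]


@dataclass
class PredictionSet:
    row_meta: pd.DataFrame
    labels: list[str]
    probabilities: np.ndarray
    threshold: float = 0.5

    @property
    def hard_labels(self) -> np.ndarray:
        return (self.probabilities >= self.threshold).astype(int)


@dataclass
class ChainModel:
    label_order: list[str]
    models: list[object]
    feature_manifest: list[list[str]]
    stacking_plan: CVPlan
    signal: str
    base_features: list[str]
    threshold: float = 0.5


@dataclass
class BinarySet:
    labels: list[str]
    models: list[object]
    base_features: list[str]
    threshold: float = 0.5


def order_labels(labels: LabelMatrix) -> list[str]:
    """Vascular first, then cardiac groups by descending positive count
    (lexicographic tiebreak)."""
    if len(labels.labels) != 7:
        raise SchemaError("expected a 7-column label matrix")
    cardiac = [name for name in labels.labels if name != "vascular_disorders"]
    counts = {name: int(labels.column(name).sum()) for name in cardiac}
    ordered = sorted(cardiac, key=lambda name: (-counts[name], name))
    return ["vascular_disorders"] + ordered


def _fit_position(
    design: np.ndarray,
    y: np.ndarray,
    spec: BaseLearnerSpec,
    config: PipelineConfig,
    seed: int,
    binary_signal_columns: list[int],
):
    if len(np.unique(y)) < 2:
        log.warning("single-class training label; fitting constant-prevalence scorer")
        return ConstantScorer(float(np.mean(y)))
    if config.smote.enabled:
        design, y = smote_oversample(
            design,
            y,
            target_ratio=config.smote.target_ratio,
            k_neighbors=config.smote.k_neighbors,
            seed=seed,
            binary_columns=binary_signal_columns,
        )
    return spec.build(seed).fit(design, y)


def fit_chain(
    features: FeatureMatrix,
    labels: LabelMatrix,
    spec: BaseLearnerSpec,
    config: PipelineConfig,
) -> ChainModel:
    """Train the 7-position chain with nested stacking."""
    config.validate()
    order = order_labels(labels)
    y_all = labels.align_rows(features.row_meta["drug_id"].tolist())
    y_all = y_all[:, [labels.labels.index(name) for name in order]]
    n = len(features.row_meta)
    x = features.values
    inner_plan = make_folds(
        features.row_meta,
        k=config.chain.stacking_inner_folds,
        strategy="leave_drug_out",
        seed=config.seed,
    )
    hard_signal = config.chain.downstream_signal == "hard_label"
    signals = np.zeros((n, 0))
    models, manifests = [], []
    base = list(features.feature_names)
    for position, label_name in enumerate(order):
        design = np.hstack([x, signals])
        y = y_all[:, position]
        signal_cols = list(range(len(base), len(base) + position)) if hard_signal else []
        seed_l = config.seed * 1000 + position
        model = _fit_position(design, y, spec, config, seed_l, signal_cols)
        models.append(model)
        manifests.append(
            base + [f"{SIGNAL_PREFIX}::{name}" for name in order[:position]]
        )
        # Out-of-fold upstream signal for downstream training inputs.
        oof = np.full(n, np.nan)
        for f, (tr, va) in enumerate(inner_plan.folds):
            tr, va = list(tr), list(va)
            fold_model = _fit_position(
                design[tr], y[tr], spec, config, seed_l * 100 + f, signal_cols
            )
            oof[va] = _positive_proba(fold_model, design[va])
        assert not np.isnan(oof).any()
        column = (oof >= 0.5).astype(float) if hard_signal else oof
        signals = np.column_stack([signals, column])
    return ChainModel(
        label_order=order,
        models=models,
        feature_manifest=manifests,
        stacking_plan=inner_plan,
        signal=config.chain.downstream_signal,
        base_features=base,
    )


def predict_chain(model: ChainModel, features: FeatureMatrix) -> PredictionSet:
    """Score labels in chain order, feeding emitted signals downstream."""
    if set(model.base_features) - set(features.feature_names):
        raise SchemaError("feature columns do not match the model manifest")
    aligned = features.reindex_columns(model.base_features)
    x = aligned.values
    n = len(aligned.row_meta)
    hard_signal = model.signal == "hard_label"
    signals = np.zeros((n, 0))
    probabilities = np.zeros((n, len(model.label_order)))
    for position, fitted in enumerate(model.models):
        design = np.hstack([x, signals])
        prob = _positive_proba(fitted, design)
        probabilities[:, position] = prob
        column = (prob >= model.threshold).astype(float) if hard_signal else prob
        signals = np.column_stack([signals, column])
    return PredictionSet(
        row_meta=aligned.row_meta.copy(),
        labels=list(model.label_order),
        probabilities=probabilities,
        threshold=model.threshold,
    )


def fit_binary_set(
    features: FeatureMatrix,
    labels: LabelMatrix,
    spec: BaseLearnerSpec,
    config: PipelineConfig,
) -> BinarySet:
    """Independent per-label classifiers: same contract, no upstream signals."""
    config.validate()
    order = order_labels(labels)
    y_all = labels.align_rows(features.row_meta["drug_id"].tolist())
    y_all = y_all[:, [labels.labels.index(name) for name in order]]
    models = []
    for position, label_name in enumerate(order):
        seed_l = config.seed * 1000 + position
        models.append(
            _fit_position(features.values, y_all[:, position], spec, config, seed_l, [])
        )
    return BinarySet(
        labels=order, models=models, base_features=list(features.feature_names)
    )


def predict_binary_set(model: BinarySet, features: FeatureMatrix) -> PredictionSet:
    if set(model.base_features) - set(features.feature_names):
        raise SchemaError("feature columns do not match the model manifest")
    aligned = features.reindex_columns(model.base_features)
    probabilities = np.column_stack(
        [_positive_proba(fitted, aligned.values) for fitted in model.models]
    )
    return PredictionSet(
        row_meta=aligned.row_meta.copy(),
        labels=list(model.labels),
        probabilities=probabilities,
        threshold=model.threshold,
    )


def verify_no_leakage(model: ChainModel, row_meta: pd.DataFrame) -> bool:
    """Assert the stacking plan never scores a drug's rows with a model that
    saw that drug during the inner fit."""
    drug_ids = row_meta["drug_id"].to_numpy()
    for tr, va in model.stacking_plan.folds:
        if set(drug_ids[list(tr)]) & set(drug_ids[list(va)]):
            return False
    return True
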