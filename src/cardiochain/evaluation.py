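"""Metrics, cross-validation engines, SMOTE, Latin-hypercube tuning, reports.

Conventions mirrored from the modeling protocol: Matthews correlation with the
zero-denominator -> 0 convention, rank-based AUC with ties counted one half,
Cohen's Kappa with a large-sample independence-null Z-test, aggregate metrics
reported as mean +/- 0.5 standard deviation over the six cardiac labels
(the vascular chain-seed label is always excluded from aggregates).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, qmc, rankdata
from sklearn.neighbors import NearestNeighbors

from .datamodel import (
    CARDIAC_GROUPS,
    ConfigValidationError,
    LabelMatrix,
    UndefinedMetricError,
)

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Confusion-count metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @staticmethod
    def from_vectors(truth: np.ndarray, predicted: np.ndarray) -> "ConfusionCounts":
        truth = np.asarray(truth, dtype=int)
        predicted = np.asarray(predicted, dtype=int)
        return ConfusionCounts(
            tp=int(((truth == 1) & (predicted == 1)).sum()),
            tn=int(((truth == 0) & (predicted == 0)).sum()),
            fp=int(((truth == 0) & (predicted == 1)).sum()),
            fn=int(((truth == 1) & (predicted == 0)).sum()),
        )


def matthews_cc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    num = c.tp * c.tn - c.fp * c.fn
    den = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if den == 0:
        return 0.0
    return num / math.sqrt(den)


def accuracy_f1(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, f1); 0 on empty denominators, logged."""
    if c.total == 0:
        raise UndefinedMetricError("no evaluated rows")
    accuracy = (c.tp + c.tn) / c.total
    if c.tp + c.fp == 0:
        log.debug("precision denominator empty; reporting 0")
        precision = 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        log.debug("recall denominator empty; reporting 0")
        recall = 0.0
    else:
        recall = c.tp / (c.tp + c.fn)
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return accuracy, precision, recall, f1


def auc(scores: Sequence[float], truth: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: one class absent")
    ranks = rankdata(scores)
    u = ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


# --------------------------------------------------------------------------
# Cohen's Kappa
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p_o: float
    p_e: float
    z: float
    p_value: float


def cohen_kappa(a: Sequence[int], b: Sequence[int]) -> KappaResult:
    """Chance-corrected agreement between two binary vectors with a Z-test.

    kappa = 1 - (1 - p_o) / (1 - p_e) with p_o the observed agreement and
    p_e = sum_c marginal_a(c) * marginal_b(c).  The Z statistic uses the
    standard large-sample variance of kappa under the independence null.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 positions")
    p_o = float((a == b).mean())
    pa = np.array([(a == 0).mean(), (a == 1).mean()])
    pb = np.array([(b == 0).mean(), (b == 1).mean()])
    p_e = float((pa * pb).sum())
    if p_e >= 1.0:
        raise UndefinedMetricError("kappa undefined: expected agreement is 1")
    kappa = 1.0 - (1.0 - p_o) / (1.0 - p_e)
    var0 = (p_e + p_e**2 - float((pa * pb * (pa + pb)).sum())) / (
        n * (1.0 - p_e) ** 2
    )
    if var0 <= 0:
        z = 0.0 if kappa == 0 else math.copysign(math.inf, kappa)
    else:
        z = kappa / math.sqrt(var0)
    p_value = float(2 * norm.sf(abs(z))) if math.isfinite(z) else 0.0
    return KappaResult(kappa=float(kappa), p_o=p_o, p_e=p_e, z=float(z), p_value=p_value)


# --------------------------------------------------------------------------
# Cross-validation plans
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CVPlan:
    strategy: str
    folds: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]

    def validate_partition(self, n_rows: int) -> None:
        seen = sorted(i for _, va in self.folds for i in va)
        if seen != list(range(n_rows)):
            raise ValueError("validation folds do not partition the rows")


def make_folds(
    row_meta: pd.DataFrame, k: int, strategy: str, seed: int
) -> CVPlan:
    """Deal rows into k near-equal folds.

    leave_drug_out: drugs are shuffled and dealt into k groups; every row
    follows its drug, so no drug straddles a train/validation boundary.
    random: rows are shuffled and dealt regardless of drug.
    """
    if k < 2:
        raise ConfigValidationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    drug_ids = row_meta["drug_id"].to_numpy()
    n = len(drug_ids)
    all_rows = np.arange(n)
    folds = []
    if strategy == "leave_drug_out":
        drugs = pd.unique(drug_ids)
        if len(drugs) < k:
            raise ConfigValidationError(
                f"leave_drug_out needs >= {k} distinct drugs, got {len(drugs)}"
            )
        shuffled = rng.permutation(drugs)
        for chunk in np.array_split(shuffled, k):
            va_mask = np.isin(drug_ids, chunk)
            folds.append(
                (tuple(all_rows[~va_mask].tolist()), tuple(all_rows[va_mask].tolist()))
            )
    elif strategy == "random":
        shuffled = rng.permutation(all_rows)
        for chunk in np.array_split(shuffled, k):
            va_mask = np.isin(all_rows, chunk)
            folds.append(
                (tuple(all_rows[~va_mask].tolist()), tuple(all_rows[va_mask].tolist()))
            )
    else:
        raise ConfigValidationError(f"unknown CV strategy {strategy!r}")
    plan = CVPlan(strategy=strategy, folds=tuple(folds))
    plan.validate_partition(n)
    return plan


# --------------------------------------------------------------------------
# SMOTE
# --------------------------------------------------------------------------

def smote_oversample(
    design: np.ndarray,
    label: np.ndarray,
    target_ratio: float = 1.0,
    k_neighbors: int = 5,
    seed: int = 0,
    binary_columns: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Append synthetic minority rows x + u * (x_nn - x), u ~ Uniform(0, 1).

    Neighbours are the k nearest minority rows in Euclidean distance.  The
    original rows are never modified.  Columns listed in ``binary_columns``
    (e.g. hard-label chain signals) are re-thresholded at 0.5 after
    interpolation.  A minority with fewer than 2 rows skips augmentation
    with a warning.
    """
    design = np.asarray(design, dtype=float)
    label = np.asarray(label, dtype=int)
    counts = np.bincount(label, minlength=2)
    minority = int(np.argmin(counts))
    n_min, n_maj = counts[minority], counts[1 - minority]
    if n_min < 2:
        log.warning("SMOTE skipped: minority class has %d row(s)", n_min)
        return design, label
    n_needed = int(math.ceil(target_ratio * n_maj)) - n_min
    if n_needed <= 0:
        return design, label
    rng = np.random.default_rng(seed)
    x_min = design[label == minority]
    k = min(k_neighbors, n_min - 1)
    if k < k_neighbors:
        log.warning("SMOTE k_neighbors reduced from %d to %d", k_neighbors, k)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x_min)
    neighbor_idx = nn.kneighbors(x_min, return_distance=False)[:, 1:]
    base = rng.integers(0, n_min, size=n_needed)
    pick = rng.integers(0, k, size=n_needed)
    u = rng.uniform(size=(n_needed, 1))
    x = x_min[base]
    x_nn = x_min[neighbor_idx[base, pick]]
    synthetic = x + u * (x_nn - x)
    if binary_columns is not None and len(binary_columns):
        cols = np.asarray(list(binary_columns), dtype=int)
        synthetic[:, cols] = (synthetic[:, cols] >= 0.5).astype(float)
    out_design = np.vstack([design, synthetic])
    out_label = np.concatenate([label, np.full(n_needed, minority, dtype=int)])
    return out_design, out_label


# --------------------------------------------------------------------------
# Latin hypercube tuning
# --------------------------------------------------------------------------

def lhs_sample(
    space: Mapping[str, tuple[float, float]], n_samples: int, seed: int
) -> list[dict[str, float]]:
    """n_samples Latin-hypercube points over a box; int bounds -> int params."""
    if n_samples < 1:
        raise ConfigValidationError("n_samples must be >= 1")
    names = list(space)
    for name, (lo, hi) in space.items():
        if not (math.isfinite(lo) and math.isfinite(hi)) or hi < lo:
            raise ConfigValidationError(f"unbounded or invalid range for {name!r}")
    unit = qmc.LatinHypercube(d=len(names), seed=seed).random(n_samples)
    points = []
    for row in unit:
        params = {}
        for j, name in enumerate(names):
            lo, hi = space[name]
            value = lo + row[j] * (hi - lo)
            if float(lo).is_integer() and float(hi).is_integer() and isinstance(lo, int):
                value = int(round(value))
            params[name] = value
        points.append(params)
    return points


def lhs_tune(
    space: Mapping[str, tuple[float, float]],
    n_samples: int,
    objective: Callable[[dict[str, float]], float],
    seed: int,
) -> tuple[dict[str, float], list[tuple[dict[str, float], float]]]:
    """Maximize ``objective`` over an LHS design; ties -> first encountered."""
    points = lhs_sample(space, n_samples, seed)
    history = []
    best_params, best_score = None, -math.inf
    for params in points:
        score = float(objective(params))
        history.append((params, score))
        if score > best_score:
            best_params, best_score = params, score
    return best_params, history


# --------------------------------------------------------------------------
# Reports
# --------------------------------------------------------------------------

@dataclass
class LabelMetrics:
    auc: float | None
    mcc: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    counts: ConfusionCounts


@dataclass
class MetricsReport:
    labels: list[str]
    per_label: dict[str, LabelMetrics]
    aggregate: dict[str, float]
    kappa_true: pd.DataFrame | None = None
    kappa_pred: pd.DataFrame | None = None
    context: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.labels:
            m = self.per_label[name]
            rows.append(
                {
                    "label": name,
                    "auc": m.auc,
                    "mcc": m.mcc,
                    "accuracy": m.accuracy,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                    "tp": m.counts.tp,
                    "tn": m.counts.tn,
                    "fp": m.counts.fp,
                    "fn": m.counts.fn,
                }
            )
        return pd.DataFrame(rows)


def _mean_half_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)], float)
    if arr.size == 0:
        return math.nan, math.nan
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), 0.5 * sd


def evaluate(
    predictions,
    labels: LabelMatrix,
    threshold: float = 0.5,
    context: str = "",
) -> MetricsReport:
    """Per-label metrics at profile level with mean +/- 0.5 SD aggregates.

    ``predictions`` is a PredictionSet (row_meta + per-label probabilities and
    hard labels).  The vascular label is reported but excluded from the
    aggregate; one-class labels get AUC None and drop out of the mean.
    """
    truth = labels.align_rows(predictions.row_meta["drug_id"].tolist())
    truth = truth[:, [labels.labels.index(name) for name in predictions.labels]]
    per_label: dict[str, LabelMetrics] = {}
    for j, name in enumerate(predictions.labels):
        y = truth[:, j]
        prob = predictions.probabilities[:, j]
        hard = (prob >= threshold).astype(int)
        counts = ConfusionCounts.from_vectors(y, hard)
        accuracy, precision, recall, f1 = accuracy_f1(counts)
        try:
            label_auc = auc(prob, y)
        except UndefinedMetricError:
            log.warning("label %s: AUC undefined (one class); excluded from mean", name)
            label_auc = None
        per_label[name] = LabelMetrics(
            auc=label_auc,
            mcc=matthews_cc(counts),
            accuracy=accuracy,
            precision=precision,
            recall=recall,
            f1=f1,
            counts=counts,
        )
    cardiac = [n for n in predictions.labels if n in CARDIAC_GROUPS]
    agg: dict[str, float] = {}
    for metric in ("auc", "mcc", "accuracy", "f1"):
        values = [getattr(per_label[n], metric) for n in cardiac]
        mean, half_sd = _mean_half_sd(values)
        agg[f"mean_{metric}"] = mean
        agg[f"half_sd_{metric}"] = half_sd
        agg[f"sd_{metric}"] = 2 * half_sd
    report = MetricsReport(
        labels=list(predictions.labels),
        per_label=per_label,
        aggregate=agg,
        context=context,
    )
    if len(cardiac) >= 2:
        pred_hard = (predictions.probabilities >= threshold).astype(int)
        cols = [predictions.labels.index(n) for n in cardiac]
        report.kappa_pred = kappa_matrix(pred_hard[:, cols], cardiac)
        report.kappa_true = kappa_matrix(truth[:, cols], cardiac)
    return report


def kappa_matrix(values: np.ndarray, names: Sequence[str]) -> pd.DataFrame:
    """Pairwise Cohen's Kappa grid; undefined entries masked as NaN."""
    k = values.shape[1]
    grid = np.full((k, k), np.nan)
    for i in range(k):
        grid[i, i] = 1.0
        for j in range(i + 1, k):
            try:
                grid[i, j] = grid[j, i] = cohen_kappa(values[:, i], values[:, j]).kappa
            except UndefinedMetricError:
                pass
    return pd.DataFrame(grid, index=list(names), columns=list(names))


def relationship_preservation(
    predictions, labels: LabelMatrix, threshold: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(kappa_pred, kappa_true, difference) over the six cardiac labels."""
    cardiac = [n for n in predictions.labels if n in CARDIAC_GROUPS]
    cols = [predictions.labels.index(n) for n in cardiac]
    pred_hard = (predictions.probabilities[:, cols] >= threshold).astype(int)
    truth = labels.align_rows(predictions.row_meta["drug_id"].tolist())
    truth = truth[:, [labels.labels.index(n) for n in cardiac]]
    kappa_pred = kappa_matrix(pred_hard, cardiac)
    kappa_true = kappa_matrix(truth, cardiac)
    return kappa_pred, kappa_true, kappa_pred - kappa_true


def kappa_frobenius_distance(kappa_pred: pd.DataFrame, kappa_true: pd.DataFrame) -> float:
    """Frobenius norm of the masked difference between two Kappa grids."""
    diff = (kappa_pred - kappa_true).to_numpy()
    return float(np.sqrt(np.nansum(diff**2)))
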