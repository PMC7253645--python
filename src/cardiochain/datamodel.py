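"""Shared domain types for the cardiotoxicity prediction pipeline.

The label space is fixed: one leading vascular label (used only to seed the
classifier chain) followed by six cardiac disorder groups.  All tabular
containers are thin dataclasses around numpy arrays / pandas frames so that
every pipeline stage exchanges the same explicit structures.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Chain order: vascular first, then the six cardiac groups by descending
#: positive-drug count in the reference database.
LABEL_GROUPS: tuple[str, ...] = (
    "vascular_disorders",
    "cardiac_dis_ss",
    "cardiac_arrhythmias",
    "heart_failure",
    "coronary_artery_dis",
    "pericardial_dis",
    "myocardial_dis",
)

#: The six groups that define "unsafe" status and enter aggregate metrics.
CARDIAC_GROUPS: tuple[str, ...] = LABEL_GROUPS[1:]

DRUG_STATUSES = frozenset({"approved", "withdrawn", "investigational", "other"})
THERAPEUTIC_CLASSES = frozenset(
    {"antineoplastic", "cardiovascular", "cns", "anti_inflammatory", "other"}
)

ROW_META_COLUMNS = ("drug_id", "cell_line", "time_h", "concentration")


class SchemaError(ValueError):
    """A table is missing required columns or is structurally malformed."""


class IntegrityError(ValueError):
    """Cross-record consistency violated (duplicate ids, dangling references)."""


class ConfigValidationError(ValueError):
    """Configuration value outside its documented domain."""


class StructureError(ValueError):
    """A molecular structure could not be parsed or processed."""


class SelectionError(ValueError):
    """Feature selection preconditions violated (e.g. constant label)."""


class UndefinedMetricError(ValueError):
    """A metric is mathematically undefined for the given inputs."""


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    smiles: str | None = None
    status: str = "other"
    targets: frozenset[str] = field(default_factory=frozenset)
    therapeutic_class: str | None = None
    flagged: bool = False  # set when the SMILES fails to parse downstream

    def __post_init__(self) -> None:
        if self.status not in DRUG_STATUSES:
            raise ConfigValidationError(
                f"drug {self.drug_id!r}: unknown status {self.status!r}"
            )
        if (
            self.therapeutic_class is not None
            and self.therapeutic_class not in THERAPEUTIC_CLASSES
        ):
            raise ConfigValidationError(
                f"drug {self.drug_id!r}: unknown therapeutic class "
                f"{self.therapeutic_class!r}"
            )


@dataclass(frozen=True)
class SideEffectRecord:
    drug_id: str
    term_id: str
    group: str = "other"

    def __post_init__(self) -> None:
        if self.group != "other" and self.group not in LABEL_GROUPS:
            raise ConfigValidationError(f"unknown side-effect group {self.group!r}")


@dataclass(frozen=True)
class SampleProfile:
    """One well-level expression profile of a drug in one condition."""

    sample_id: str
    drug_id: str
    cell_line: str
    time_h: float
    concentration: float
    expression: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.time_h > 0:
            raise ConfigValidationError(f"sample {self.sample_id!r}: time_h must be > 0")
        if not self.concentration > 0:
            raise ConfigValidationError(
                f"sample {self.sample_id!r}: concentration must be > 0"
            )


@dataclass
class LabelMatrix:
    """Drugs x 7 ordered binary cardiotoxicity labels."""

    drug_ids: list[str]
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.shape != (len(self.drug_ids), len(self.labels)):
            raise SchemaError("label matrix shape does not match ids/labels")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise IntegrityError("duplicate drug_id in label matrix")
        if not np.isin(self.values, (0, 1)).all():
            raise SchemaError("label values must be binary")
        for name in self.labels:
            if name not in LABEL_GROUPS:
                raise SchemaError(f"unknown label group {name!r}")

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]

    def row(self, drug_id: str) -> np.ndarray:
        return self.values[self.drug_ids.index(drug_id)]

    def align_rows(self, drug_ids: Sequence[str]) -> np.ndarray:
        """Label rows for an arbitrary (repeating) drug_id sequence."""
        index = {d: i for i, d in enumerate(self.drug_ids)}
        try:
            rows = [index[d] for d in drug_ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise IntegrityError(f"drug {exc.args[0]!r} not in label matrix") from exc
        return self.values[rows]

    def reorder(self, labels: Sequence[str]) -> "LabelMatrix":
        cols = [self.labels.index(name) for name in labels]
        return LabelMatrix(list(self.drug_ids), list(labels), self.values[:, cols])

    def subset(self, drug_ids: Sequence[str]) -> "LabelMatrix":
        return LabelMatrix(list(drug_ids), list(self.labels), self.align_rows(drug_ids))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.labels)
        frame.insert(0, "drug_id", self.drug_ids)
        return frame


@dataclass
class FeatureMatrix:
    """Profiles x features, with feature names partitioned into named blocks.

    Canonical block order is transcriptional -> descriptors -> fingerprint,
    yielding the reproducible dense layout the models consume.
    """

    row_meta: pd.DataFrame
    feature_names: list[str]
    values: np.ndarray
    blocks: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        missing = [c for c in ROW_META_COLUMNS if c not in self.row_meta.columns]
        if missing:
            raise SchemaError(f"row_meta missing columns {missing}")
        if self.values.shape != (len(self.row_meta), len(self.feature_names)):
            raise SchemaError("feature matrix shape mismatch")
        blocked = [f for names in self.blocks.values() for f in names]
        if blocked and blocked != self.feature_names:
            raise SchemaError("blocks must partition feature_names in order")
        if "descriptors" in self.blocks and len(self.blocks["descriptors"]) != 7:
            raise SchemaError("descriptor block must have exactly 7 columns")
        if "fingerprint" in self.blocks:
            names = self.blocks["fingerprint"]
            if len(names) != 79:
                raise SchemaError("fingerprint block must have exactly 79 columns")
            bits = self.block_values("fingerprint")
            if not np.isin(bits, (0.0, 1.0)).all():
                raise SchemaError("fingerprint block must be binary")

    @property
    def drug_ids(self) -> np.ndarray:
        return self.row_meta["drug_id"].to_numpy()

    def block_values(self, block: str) -> np.ndarray:
        names = self.blocks[block]
        cols = [self.feature_names.index(n) for n in names]
        return self.values[:, cols]

    def select_rows(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.row_meta.iloc[mask].reset_index(drop=True),
            list(self.feature_names),
            self.values[mask],
            {k: list(v) for k, v in self.blocks.items()},
        )

    def reindex_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column-permuted copy; raises SchemaError on any missing name."""
        try:
            cols = [self.feature_names.index(n) for n in names]
        except ValueError as exc:
            raise SchemaError(f"feature column not found: {exc}") from exc
        return FeatureMatrix(
            self.row_meta.copy(), list(names), self.values[:, cols], {}
        )

    def check_against_labels(self, labels: LabelMatrix) -> None:
        known = set(labels.drug_ids)
        dangling = sorted(set(self.drug_ids) - known)
        if dangling:
            raise IntegrityError(f"feature rows reference unknown drugs: {dangling[:5]}")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        return pd.concat([self.row_meta.reset_index(drop=True), frame], axis=1)


def hstack_features(left: FeatureMatrix, right: FeatureMatrix) -> FeatureMatrix:
    """Column-concatenate two row-aligned feature matrices, merging blocks."""
    if len(left.row_meta) != len(right.row_meta):
        raise SchemaError("cannot hstack feature matrices with different row counts")
    blocks = {k: list(v) for k, v in left.blocks.items()}
    for k, v in right.blocks.items():
        if k in blocks:
            raise SchemaError(f"duplicate block {k!r}")
        blocks[k] = list(v)
    return FeatureMatrix(
        left.row_meta.copy(),
        list(left.feature_names) + list(right.feature_names),
        np.hstack([left.values, right.values]),
        blocks,
    )


# --------------------------------------------------------------------------
# Pipeline configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CVConfig:
    k_folds: int = 5
    strategy: str = "leave_drug_out"


@dataclass(frozen=True)
class SmoteConfig:
    enabled: bool = True
    target_ratio: float = 1.0
    k_neighbors: int = 5


@dataclass(frozen=True)
class TuningConfig:
    n_lhs_samples: int = 10
    objective: str = "mean_mcc"


@dataclass(frozen=True)
class ChainConfig:
    stacking_inner_folds: int = 5
    downstream_signal: str = "hard_label"


@dataclass(frozen=True)
class BaseLearnerConfig:
    family: str = "random_forest"
    hyperparameters: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    cv: CVConfig = field(default_factory=CVConfig)
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    tuning: TuningConfig = field(default_factory=TuningConfig)
    chain: ChainConfig = field(default_factory=ChainConfig)
    base_learner: BaseLearnerConfig = field(default_factory=BaseLearnerConfig)

    def validate(self) -> "PipelineConfig":
        problems = []
        if self.cv.k_folds < 2:
            problems.append("cv.k_folds must be >= 2")
        if self.cv.strategy not in ("leave_drug_out", "random"):
            problems.append(f"cv.strategy invalid: {self.cv.strategy!r}")
        if not (0 < self.smote.target_ratio <= 1):
            problems.append("smote.target_ratio must be in (0, 1]")
        if self.smote.k_neighbors < 1:
            problems.append("smote.k_neighbors must be >= 1")
        if self.tuning.n_lhs_samples < 1:
            problems.append("tuning.n_lhs_samples must be >= 1")
        if self.chain.stacking_inner_folds < 2:
            problems.append("chain.stacking_inner_folds must be >= 2")
        if self.chain.downstream_signal not in ("hard_label", "probability"):
            problems.append(
                f"chain.downstream_signal invalid: {self.chain.downstream_signal!r}"
            )
        if self.base_learner.family not in (
            "penalized_logistic",
            "random_forest",
            "gradient_boosting",
        ):
            problems.append(f"base_learner.family invalid: {self.base_learner.family!r}")
        if problems:
            raise ConfigValidationError("; ".join(problems))
        return self

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed)
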