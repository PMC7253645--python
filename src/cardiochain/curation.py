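"""Dataset-construction rules: labeling, safe-control selection, sample
collapsing and the target-aware train/test split.

A drug is "unsafe" when any of the six cardiac label groups is set; the
vascular label only seeds the classifier chain.  Safe controls must be
approved drugs with no cardiac record that share at least one protein target
with some unsafe drug (zero-label non-approved drugs are dropped, mirroring
the withdrawn-safe filter).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    CARDIAC_GROUPS,
    ConfigValidationError,
    DrugRecord,
    FeatureMatrix,
    hstack_features,
    IntegrityError,
    LABEL_GROUPS,
    LabelMatrix,
    SampleProfile,
    SideEffectRecord,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitPlan:
    train_drugs: frozenset[str]
    test_drugs: frozenset[str]

    def __post_init__(self) -> None:
        if self.train_drugs & self.test_drugs:
            raise IntegrityError("train and test drug sets overlap")


def label_drugs(
    drugs: list[DrugRecord], effects: list[SideEffectRecord]
) -> LabelMatrix:
    """drug x group matrix: cell = 1 iff >= 1 effect record of that group."""
    drug_ids = [d.drug_id for d in drugs]
    index = {d: i for i, d in enumerate(drug_ids)}
    values = np.zeros((len(drug_ids), len(LABEL_GROUPS)), dtype=int)
    col = {g: j for j, g in enumerate(LABEL_GROUPS)}
    for record in effects:
        if record.drug_id not in index:
            raise IntegrityError(
                f"effect record references unknown drug {record.drug_id!r}"
            )
        if record.group in col:
            values[index[record.drug_id], col[record.group]] = 1
    return LabelMatrix(drug_ids, list(LABEL_GROUPS), values)


def is_unsafe(labels: LabelMatrix) -> np.ndarray:
    """Boolean per drug: any of the six cardiac groups set."""
    cols = [labels.labels.index(g) for g in CARDIAC_GROUPS]
    return labels.values[:, cols].any(axis=1)


def select_safe_controls(
    drugs: list[DrugRecord], labels: LabelMatrix
) -> set[str]:
    """Approved zero-cardiac-label drugs sharing >= 1 target with an unsafe drug."""
    unsafe = is_unsafe(labels)
    by_id = {d.drug_id: d for d in drugs}
    unsafe_targets: set[str] = set()
    for drug_id, flag in zip(labels.drug_ids, unsafe):
        if flag:
            unsafe_targets |= by_id[drug_id].targets
    controls = set()
    n_dropped_status = 0
    for drug_id, flag in zip(labels.drug_ids, unsafe):
        if flag:
            continue
        record = by_id[drug_id]
        if record.status != "approved":
            n_dropped_status += 1
            continue
        if record.targets & unsafe_targets:
            controls.add(drug_id)
    if n_dropped_status:
        log.info("excluded %d zero-label drugs with non-approved status", n_dropped_status)
    return controls


def collapse_samples(profiles: list[SampleProfile]) -> FeatureMatrix:
    """Average replicate wells into one row per (drug, cell_line, time, conc)."""
    if not profiles:
        raise ConfigValidationError("no profiles to collapse")
    genes = list(profiles[0].expression)
    rows = pd.DataFrame(
        {
            "drug_id": [p.drug_id for p in profiles],
            "cell_line": [p.cell_line for p in profiles],
            "time_h": [p.time_h for p in profiles],
            "concentration": [p.concentration for p in profiles],
        }
    )
    expr = pd.DataFrame([list(p.expression.values()) for p in profiles], columns=genes)
    if any(list(p.expression) != genes for p in profiles):
        raise IntegrityError("profiles do not share an identical gene key set")
    combined = pd.concat([rows, expr], axis=1)
    grouped = (
        combined.groupby(
            ["drug_id", "cell_line", "time_h", "concentration"], sort=False
        )[genes]
        .mean()
        .reset_index()
    )
    return FeatureMatrix(
        grouped[["drug_id", "cell_line", "time_h", "concentration"]].copy(),
        genes,
        grouped[genes].to_numpy(float),
        {"transcriptional": list(genes)},
    )


def split_by_targets(
    drugs: list[DrugRecord],
    labels: LabelMatrix,
    test_fraction: float,
    seed: int,
    max_attempts: int = 100,
) -> SplitPlan:
    """Random drug split with a target-sharing verification pass.

    Drugs are shuffled under ``seed`` and the first ``round(test_fraction*n)``
    form the test set.  If any test drug with targets shares none of them with
    a train drug the draw is repeated (up to ``max_attempts``); the best draw
    seen is returned with a warning if the constraint cannot be met.
    """
    if not 0 < test_fraction < 1:
        raise ConfigValidationError("test_fraction must be in (0, 1)")
    drug_ids = [d.drug_id for d in drugs]
    n_test = int(round(test_fraction * len(drug_ids)))
    if n_test == 0 or n_test == len(drug_ids):
        raise ConfigValidationError("test_fraction produces an empty train or test side")
    by_id = {d.drug_id: d for d in drugs}
    rng = np.random.default_rng(seed)
    best: tuple[int, SplitPlan] | None = None
    for _ in range(max_attempts):
        order = rng.permutation(drug_ids)
        test = frozenset(order[:n_test])
        train = frozenset(order[n_test:])
        train_targets = set().union(*(by_id[d].targets for d in train))
        unlinked = sum(
            1
            for d in test
            if by_id[d].targets and not (by_id[d].targets & train_targets)
        )
        plan = SplitPlan(train_drugs=train, test_drugs=test)
        if unlinked == 0:
            return plan
        if best is None or unlinked < best[0]:
            best = (unlinked, plan)
    log.warning(
        "target-linked split not achievable in %d attempts; %d test drugs unlinked",
        max_attempts,
        best[0],
    )
    return best[1]


def join_molecular(
    transcriptional: FeatureMatrix, molecular: FeatureMatrix
) -> FeatureMatrix:
    """Broadcast the per-drug molecular block onto collapsed profile rows."""
    mol_index = {d: i for i, d in enumerate(molecular.row_meta["drug_id"])}
    try:
        rows = [mol_index[d] for d in transcriptional.row_meta["drug_id"]]
    except KeyError as exc:
        raise IntegrityError(f"no molecular row for drug {exc.args[0]!r}") from exc
    broadcast = FeatureMatrix(
        transcriptional.row_meta.copy(),
        list(molecular.feature_names),
        molecular.values[rows],
        {k: list(v) for k, v in molecular.blocks.items()},
    )
    return hstack_features(transcriptional, broadcast)
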