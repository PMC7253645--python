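"""Tabular readers and writers (UTF-8, tab-separated, '.' decimal, header row).

All loaders are deterministic and preserve row order.  Writers round-trip:
metadata exactly, floating point values to full ``repr`` precision.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    BaseLearnerConfig,
    ChainConfig,
    CVConfig,
    DrugRecord,
    FeatureMatrix,
    IntegrityError,
    LabelMatrix,
    LABEL_GROUPS,
    PipelineConfig,
    ROW_META_COLUMNS,
    SampleProfile,
    SchemaError,
    SideEffectRecord,
    SmoteConfig,
    TuningConfig,
    DRUG_STATUSES,
    THERAPEUTIC_CLASSES,
)

log = logging.getLogger(__name__)

_SEP = "\t"

DRUG_COLUMNS = ("drug_id", "smiles", "status", "targets", "therapeutic_class")
EFFECT_COLUMNS = ("drug_id", "term_id")
EXPRESSION_META = ("sample_id",) + ROW_META_COLUMNS


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_SEP, dtype=str, keep_default_na=False)


def _require_columns(frame: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what}: missing required columns {missing}")


# --------------------------------------------------------------------------
# Drug table
# --------------------------------------------------------------------------

def read_drug_table(path: str | Path) -> list[DrugRecord]:
    frame = _read_tsv(path)
    _require_columns(frame, DRUG_COLUMNS, "drug table")
    dupes = frame["drug_id"][frame["drug_id"].duplicated()].tolist()
    if dupes:
        raise IntegrityError(f"duplicate drug_id values: {sorted(set(dupes))}")
    records = []
    for row in frame.itertuples(index=False):
        status = row.status.strip() or "other"
        if status not in DRUG_STATUSES:
            log.warning("drug %s: status %r mapped to 'other'", row.drug_id, status)
            status = "other"
        tclass = row.therapeutic_class.strip() or None
        if tclass is not None and tclass not in THERAPEUTIC_CLASSES:
            log.warning(
                "drug %s: therapeutic class %r mapped to 'other'", row.drug_id, tclass
            )
            tclass = "other"
        targets = frozenset(t for t in row.targets.split(";") if t)
        records.append(
            DrugRecord(
                drug_id=row.drug_id,
                smiles=row.smiles or None,
                status=status,
                targets=targets,
                therapeutic_class=tclass,
            )
        )
    return records


def write_drug_table(records: Sequence[DrugRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "drug_id": [r.drug_id for r in records],
            "smiles": [r.smiles or "" for r in records],
            "status": [r.status for r in records],
            "targets": [";".join(sorted(r.targets)) for r in records],
            "therapeutic_class": [r.therapeutic_class or "" for r in records],
        }
    )
    frame.to_csv(path, sep=_SEP, index=False)


# --------------------------------------------------------------------------
# Side effects and the term hierarchy
# --------------------------------------------------------------------------

def read_term_hierarchy(path: str | Path) -> dict[str, str]:
    """Two-column table term_id -> group; unknown groups rejected."""
    frame = _read_tsv(path)
    _require_columns(frame, ("term_id", "group"), "term hierarchy")
    mapping: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        if row.group not in LABEL_GROUPS and row.group != "other":
            raise SchemaError(f"hierarchy maps {row.term_id!r} to unknown group {row.group!r}")
        mapping[row.term_id] = row.group
    return mapping


def read_side_effect_table(
    path: str | Path, hierarchy: str | Path | dict[str, str]
) -> list[SideEffectRecord]:
    if not isinstance(hierarchy, dict):
        hierarchy = read_term_hierarchy(hierarchy)
    frame = _read_tsv(path)
    _require_columns(frame, EFFECT_COLUMNS, "side-effect table")
    records = []
    n_unmapped = 0
    for row in frame.itertuples(index=False):
        group = hierarchy.get(row.term_id)
        if group is None:
            n_unmapped += 1
            group = "other"
        records.append(SideEffectRecord(row.drug_id, row.term_id, group))
    if n_unmapped:
        log.warning("%d side-effect records with unmapped terms kept as group=other", n_unmapped)
    return records


def write_side_effect_table(records: Sequence[SideEffectRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "drug_id": [r.drug_id for r in records],
            "term_id": [r.term_id for r in records],
        }
    ).to_csv(path, sep=_SEP, index=False)


def write_term_hierarchy(mapping: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"term_id": list(mapping), "group": [mapping[t] for t in mapping]}
    ).to_csv(path, sep=_SEP, index=False)


# --------------------------------------------------------------------------
# Expression profiles
# --------------------------------------------------------------------------

def read_expression_table(
    path: str | Path, impute: str | None = None
) -> list[SampleProfile]:
    """Wide table: sample/drug/cell/time/concentration metadata + gene columns.

    Missing expression cells are a hard error unless ``impute='median'``, in
    which case the per-gene median over the table is substituted.
    """
    frame = pd.read_csv(path, sep=_SEP)
    _require_columns(frame, EXPRESSION_META, "expression table")
    gene_cols = [c for c in frame.columns if c not in EXPRESSION_META]
    if not gene_cols:
        raise SchemaError("expression table has no gene columns")
    expr = frame[gene_cols]
    if not all(np.issubdtype(d, np.number) for d in expr.dtypes):
        bad = [c for c, d in expr.dtypes.items() if not np.issubdtype(d, np.number)]
        raise SchemaError(f"non-numeric expression columns: {bad}")
    if expr.isna().any().any():
        if impute == "median":
            n = int(expr.isna().sum().sum())
            expr = expr.fillna(expr.median())
            log.warning("imputed %d missing expression cells with per-gene medians", n)
        else:
            raise SchemaError("expression table contains missing values (imputation disabled)")
    profiles = []
    for i, row in enumerate(frame.itertuples(index=False)):
        profiles.append(
            SampleProfile(
                sample_id=str(row.sample_id),
                drug_id=str(row.drug_id),
                cell_line=str(row.cell_line),
                time_h=float(row.time_h),
                concentration=float(row.concentration),
                expression=dict(zip(gene_cols, expr.iloc[i].astype(float))),
            )
        )
    return profiles


def write_expression_table(profiles: Sequence[SampleProfile], path: str | Path) -> None:
    if not profiles:
        raise SchemaError("cannot write an empty expression table")
    genes = list(profiles[0].expression)
    rows = []
    for p in profiles:
        if list(p.expression) != genes:
            raise SchemaError("profiles do not share an identical gene key set")
        rows.append(
            {
                "sample_id": p.sample_id,
                "drug_id": p.drug_id,
                "cell_line": p.cell_line,
                "time_h": p.time_h,
                "concentration": p.concentration,
                **p.expression,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=_SEP, index=False)


# --------------------------------------------------------------------------
# Label and feature matrices
# --------------------------------------------------------------------------

def read_label_matrix(path: str | Path) -> LabelMatrix:
    frame = pd.read_csv(path, sep=_SEP)
    _require_columns(frame, ("drug_id",), "label matrix")
    labels = [c for c in frame.columns if c != "drug_id"]
    return LabelMatrix(
        frame["drug_id"].astype(str).tolist(), labels, frame[labels].to_numpy()
    )


def write_label_matrix(labels: LabelMatrix, path: str | Path) -> None:
    labels.to_frame().to_csv(path, sep=_SEP, index=False)


def read_feature_matrix(path: str | Path, blocks_path: str | Path | None = None) -> FeatureMatrix:
    frame = pd.read_csv(path, sep=_SEP)
    _require_columns(frame, ROW_META_COLUMNS, "feature matrix")
    feature_names = [c for c in frame.columns if c not in ROW_META_COLUMNS]
    blocks: dict[str, list[str]] = {}
    if blocks_path is not None:
        bframe = _read_tsv(blocks_path)
        _require_columns(bframe, ("feature", "block"), "feature block table")
        for row in bframe.itertuples(index=False):
            blocks.setdefault(row.block, []).append(row.feature)
    return FeatureMatrix(
        frame[list(ROW_META_COLUMNS)].copy(),
        feature_names,
        frame[feature_names].to_numpy(float),
        blocks,
    )


def write_feature_matrix(
    features: FeatureMatrix, path: str | Path, blocks_path: str | Path | None = None
) -> None:
    features.to_frame().to_csv(path, sep=_SEP, index=False)
    if blocks_path is not None:
        rows = [
            {"feature": f, "block": b}
            for b, names in features.blocks.items()
            for f in names
        ]
        pd.DataFrame(rows, columns=["feature", "block"]).to_csv(
            blocks_path, sep=_SEP, index=False
        )


def read_gene_pathway_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (gene, pathway_id) -> gene -> set of pathway ids."""
    frame = _read_tsv(path)
    _require_columns(frame, ("gene", "pathway_id"), "gene-pathway map")
    mapping: dict[str, set[str]] = {}
    for row in frame.itertuples(index=False):
        mapping.setdefault(row.gene, set()).add(row.pathway_id)
    return mapping


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config, filling documented defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise SchemaError("config file must contain a key-value mapping")
    return config_from_dict(data)


def config_from_dict(data: dict) -> PipelineConfig:
    def sub(name: str, cls, defaults):
        payload = data.get(name, {}) or {}
        if not isinstance(payload, dict):
            raise SchemaError(f"config section {name!r} must be a mapping")
        unknown = set(payload) - set(defaults.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"config section {name!r}: unknown keys {sorted(unknown)}")
        return cls(**{**{}, **payload})

    config = PipelineConfig(
        seed=int(data.get("seed", 0)),
        cv=sub("cv", CVConfig, CVConfig),
        smote=sub("smote", SmoteConfig, SmoteConfig),
        tuning=sub("tuning", TuningConfig, TuningConfig),
        chain=sub("chain", ChainConfig, ChainConfig),
        base_learner=sub("base_learner", BaseLearnerConfig, BaseLearnerConfig),
    )
    return config.validate()
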