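"""Synthetic drug datasets with known ground truth.

Correlated imbalanced binary labels come from a latent Gaussian threshold
(Gaussian copula) model: one multivariate-normal draw per drug, label j set
iff the j-th latent exceeds the (1 - prevalence_j) quantile.  Expression
profiles carry label-informative mean shifts plus a drug-specific random
effect shared across that drug's replicates -- the component that makes
random (non-grouped) cross-validation leak drug identity.  Molecular blocks
are statistical stand-ins: log-normal/normal descriptor columns and Bernoulli
fingerprint bits with label-dependent log-odds.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from scipy.special import expit
from scipy.stats import norm

import numpy as np
import pandas as pd

from .datamodel import (
    CARDIAC_GROUPS,
    ConfigValidationError,
    DrugRecord,
    FeatureMatrix,
    LABEL_GROUPS,
    LabelMatrix,
    SampleProfile,
    SideEffectRecord,
)

log = logging.getLogger(__name__)

N_FP_BITS = 79
DESCRIPTOR_NAMES = ("MW", "XLogP", "apol", "TopoPSA", "tpsaEfficiency", "ALogP", "AMR")

#: Valid structures cycled onto synthetic drug records so that downstream
#: SMILES-consuming code paths can run on generated tables.
_SMILES_PANEL = (
    "CCO",
    "c1ccccc1",
    "CC(=O)Oc1ccccc1C(=O)O",
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "C1CCNCC1",
    "OCC(O)CO",
    "Clc1ccccc1",
)


def _default_label_corr() -> np.ndarray:
    corr = np.full((7, 7), 0.3)
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class GeneratorConfig:
    n_drugs: int = 200
    labels: tuple[str, ...] = LABEL_GROUPS
    # Illustrative imbalance (vascular first); not asserted against any source.
    prevalence: tuple[float, ...] = (0.66, 0.45, 0.30, 0.14, 0.05, 0.08, 0.10)
    label_corr: np.ndarray = field(default_factory=_default_label_corr)
    n_genes: int = 100
    informative_genes_per_label: int = 5
    shared_informative_fraction: float = 0.0
    gene_effect_size: float = 1.0
    drug_random_effect_sd: float = 0.5
    noise_sd: float = 1.0
    cell_lines: tuple[str, ...] = ("A", "B")
    times_h: tuple[float, ...] = (6.0, 24.0)
    concentrations_per_drug: int = 1
    fp_informative_bits_per_label: int = 3
    fp_bit_logodds: float = 1.0
    fp_base_rate: float = 0.2
    n_targets: int = 30
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        self.label_corr = np.asarray(self.label_corr, dtype=float)
        if len(self.labels) != 7 or tuple(self.labels) != LABEL_GROUPS:
            raise ConfigValidationError("labels must be the 7 canonical groups in order")
        if self.label_corr.shape != (7, 7):
            raise ConfigValidationError("label_corr must be 7x7")
        if not np.allclose(self.label_corr, self.label_corr.T):
            raise ConfigValidationError("label_corr must be symmetric")
        if not np.allclose(np.diag(self.label_corr), 1.0):
            raise ConfigValidationError("label_corr must have unit diagonal")
        try:
            np.linalg.cholesky(self.label_corr)
        except np.linalg.LinAlgError as exc:
            raise ConfigValidationError("label_corr must be positive-definite") from exc
        if not all(0 < p < 1 for p in self.prevalence):
            raise ConfigValidationError("prevalence components must be in (0, 1)")
        if min(self.gene_effect_size, self.drug_random_effect_sd, self.noise_sd) < 0:
            raise ConfigValidationError("effect sizes must be >= 0")
        if not (0 <= self.shared_informative_fraction <= 1):
            raise ConfigValidationError("shared_informative_fraction must be in [0, 1]")
        if self.informative_genes_per_label > self.n_genes:
            raise ConfigValidationError("more informative genes than genes")
        if self.fp_informative_bits_per_label > N_FP_BITS:
            raise ConfigValidationError("more informative fingerprint bits than bits")
        return self


@dataclass
class GroundTruth:
    informative_gene_sets: dict[str, set[str]]
    informative_fp_bits: dict[str, set[int]]
    latent_corr: np.ndarray
    per_drug_latents: np.ndarray


@dataclass
class SyntheticBundle:
    drugs: list[DrugRecord]
    labels: LabelMatrix
    profiles: list[SampleProfile]
    molecular: FeatureMatrix
    truth: GroundTruth


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def simulate_label_structure(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[LabelMatrix, GroundTruth]:
    """Latent-Gaussian-threshold labels plus the ground truth scaffold."""
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    latents = rng.multivariate_normal(
        np.zeros(7), config.label_corr, size=config.n_drugs, method="cholesky"
    )
    thresholds = norm.ppf(1.0 - np.asarray(config.prevalence))
    values = (latents > thresholds).astype(int)
    drug_ids = [f"D{i:04d}" for i in range(config.n_drugs)]
    labels = LabelMatrix(drug_ids, list(config.labels), values)

    genes = _gene_names(config.n_genes)
    k = config.informative_genes_per_label
    n_shared = int(round(config.shared_informative_fraction * k))
    shared_pool = list(rng.choice(config.n_genes, size=n_shared, replace=False)) if n_shared else []
    remaining = np.setdiff1d(np.arange(config.n_genes), shared_pool)
    gene_sets: dict[str, set[str]] = {}
    for name in config.labels:
        own = rng.choice(remaining, size=k - n_shared, replace=False) if k > n_shared else []
        gene_sets[name] = {genes[i] for i in shared_pool} | {genes[int(i)] for i in own}
    fp_sets = {
        name: set(
            int(i)
            for i in rng.choice(N_FP_BITS, size=config.fp_informative_bits_per_label, replace=False)
        )
        for name in config.labels
    }
    truth = GroundTruth(
        informative_gene_sets=gene_sets,
        informative_fp_bits=fp_sets,
        latent_corr=np.array(config.label_corr),
        per_drug_latents=latents,
    )
    return labels, truth


def simulate_profiles(
    labels: LabelMatrix,
    truth: GroundTruth,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> list[SampleProfile]:
    """One profile per drug x cell_line x time x concentration.

    expression(g) = N(0,1) + gene_effect_size * sum_j label_j * 1[g informative_j]
                    + drug effect N(0, drug_random_effect_sd^2)   (per drug x gene,
                      shared across that drug's replicates)
                    + N(0, noise_sd^2)
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 1)
    genes = _gene_names(config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    indicator = np.zeros((7, config.n_genes))
    for j, name in enumerate(labels.labels):
        for g in truth.informative_gene_sets[name]:
            indicator[j, gene_index[g]] = 1.0
    shifts = config.gene_effect_size * labels.values @ indicator  # drugs x genes
    drug_effects = rng.normal(
        0.0, config.drug_random_effect_sd, size=(len(labels.drug_ids), config.n_genes)
    )
    concentrations = [float(c + 1) for c in range(config.concentrations_per_drug)]
    profiles = []
    for d, drug_id in enumerate(labels.drug_ids):
        for cell in config.cell_lines:
            for t in config.times_h:
                for conc in concentrations:
                    noise = rng.normal(0.0, 1.0, config.n_genes) + rng.normal(
                        0.0, config.noise_sd, config.n_genes
                    )
                    expr = shifts[d] + drug_effects[d] + noise
                    profiles.append(
                        SampleProfile(
                            sample_id=f"{drug_id}_{cell}_{t:g}h_c{conc:g}",
                            drug_id=drug_id,
                            cell_line=cell,
                            time_h=float(t),
                            concentration=conc,
                            expression=dict(zip(genes, expr.astype(float))),
                        )
                    )
    return profiles


def simulate_molecular_block(
    labels: LabelMatrix,
    truth: GroundTruth,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> FeatureMatrix:
    """Per-drug descriptor and fingerprint blocks (constant across replicates).

    Descriptors: MW, apol, TopoPSA, AMR log-normal; XLogP, ALogP normal;
    tpsaEfficiency = TopoPSA / MW.  Fingerprint bit b for a drug with labels y:
    Bernoulli(sigmoid(logit(base_rate) + fp_bit_logodds * sum_j y_j 1[b in bits_j])).
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 2)
    n = len(labels.drug_ids)
    mw = rng.lognormal(np.log(350.0), 0.3, n)
    topo = rng.lognormal(np.log(75.0), 0.5, n)
    descriptors = np.column_stack(
        [
            mw,
            rng.normal(2.5, 1.5, n),
            rng.lognormal(np.log(40.0), 0.3, n),
            topo,
            topo / mw,
            rng.normal(2.0, 1.0, n),
            rng.lognormal(np.log(90.0), 0.3, n),
        ]
    )
    bit_load = np.zeros((7, N_FP_BITS))
    for j, name in enumerate(labels.labels):
        for b in truth.informative_fp_bits[name]:
            bit_load[j, b] = 1.0
    alpha0 = np.log(config.fp_base_rate / (1.0 - config.fp_base_rate))
    logits = alpha0 + config.fp_bit_logodds * labels.values @ bit_load
    bits = (rng.uniform(size=(n, N_FP_BITS)) < expit(logits)).astype(float)
    row_meta = pd.DataFrame(
        {
            "drug_id": labels.drug_ids,
            "cell_line": "-",
            "time_h": np.nan,
            "concentration": np.nan,
        }
    )
    names = list(DESCRIPTOR_NAMES) + [f"estate_{b:02d}" for b in range(N_FP_BITS)]
    return FeatureMatrix(
        row_meta,
        names,
        np.hstack([descriptors, bits]),
        {"descriptors": list(DESCRIPTOR_NAMES), "fingerprint": names[7:]},
    )


def _simulate_drug_records(
    labels: LabelMatrix, config: GeneratorConfig, rng: np.random.Generator
) -> list[DrugRecord]:
    target_pool = [f"T{i:03d}" for i in range(config.n_targets)]
    statuses = rng.choice(
        ["approved", "withdrawn", "investigational"], size=len(labels.drug_ids),
        p=[0.85, 0.05, 0.10],
    )
    classes = rng.choice(
        ["antineoplastic", "cardiovascular", "cns", "anti_inflammatory", "other"],
        size=len(labels.drug_ids),
    )
    records = []
    for i, drug_id in enumerate(labels.drug_ids):
        n_targets = int(rng.integers(1, 4))
        targets = frozenset(rng.choice(target_pool, size=n_targets, replace=False))
        records.append(
            DrugRecord(
                drug_id=drug_id,
                smiles=_SMILES_PANEL[i % len(_SMILES_PANEL)],
                status=str(statuses[i]),
                targets=targets,
                therapeutic_class=str(classes[i]),
            )
        )
    return records


def effect_records_from_labels(
    labels: LabelMatrix,
) -> tuple[list[SideEffectRecord], dict[str, str]]:
    """Deterministic side-effect records and hierarchy realizing a LabelMatrix."""
    hierarchy = {f"TERM_{g}": g for g in LABEL_GROUPS}
    records = []
    for i, drug_id in enumerate(labels.drug_ids):
        for j, group in enumerate(labels.labels):
            if labels.values[i, j]:
                records.append(SideEffectRecord(drug_id, f"TERM_{group}", group))
    return records, hierarchy


def generate_dataset(config: GeneratorConfig) -> SyntheticBundle:
    """Complete bundle: drugs, labels, profiles, molecular block, ground truth.

    All randomness flows from ``config.seed``; the same seed reproduces the
    bundle bitwise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels, truth = simulate_label_structure(config, rng)
    profiles = simulate_profiles(labels, truth, config, rng)
    molecular = simulate_molecular_block(labels, truth, config, rng)
    drugs = _simulate_drug_records(labels, config, rng)
    unsafe_counts = {
        g: int(labels.column(g).sum()) for g in CARDIAC_GROUPS
    }
    log.info("generated %d drugs, %d profiles; positives per cardiac label: %s",
             config.n_drugs, len(profiles), unsafe_counts)
    return SyntheticBundle(drugs, labels, profiles, molecular, truth)
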