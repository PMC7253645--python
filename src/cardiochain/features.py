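"""Molecular descriptors/fingerprints and transcriptional feature selection.

Descriptor semantics follow the chemistry backend (RDKit): the backend ships
a single Crippen log P model, which backs both the XLogP and ALogP columns;
apol is the sum of atomic polarizabilities (implicit hydrogens included,
CRC values); tpsaEfficiency is TopoPSA expressed as a ratio to molecular
weight.  The 79-bit E-state fingerprint uses the backend's Hall-Kier atom
typer, which natively emits the 79-type legend (note: an isolated carbon with
four hydrogens has no type and sets no bit).
"""
from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors
from rdkit.Chem.EState import Fingerprinter

from .datamodel import (
    DrugRecord,
    FeatureMatrix,
    SchemaError,
    SelectionError,
    StructureError,
)
from .evaluation import KappaResult, cohen_kappa
from .synth import DESCRIPTOR_NAMES, N_FP_BITS

log = logging.getLogger(__name__)

# Atomic polarizabilities (10^-24 cm^3), CRC Handbook values.
_POLARIZABILITY = {
    "H": 0.666793, "C": 1.76, "N": 1.10, "O": 0.802, "F": 0.557,
    "P": 3.63, "S": 2.90, "Cl": 2.18, "Br": 3.05, "I": 5.35,
    "B": 3.03, "Si": 5.38, "Se": 3.77, "Li": 24.33, "Na": 24.11,
    "K": 43.4, "Mg": 10.6, "Ca": 22.8, "Fe": 8.4, "Zn": 5.75,
}


@dataclass(frozen=True)
class DescriptorSet:
    MW: float
    XLogP: float
    apol: float
    TopoPSA: float
    tpsaEfficiency: float
    ALogP: float
    AMR: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in DESCRIPTOR_NAMES], dtype=float)


@dataclass(frozen=True)
class EStateFingerprint:
    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != N_FP_BITS:
            raise SchemaError(f"fingerprint must have {N_FP_BITS} bits")
        if any(b not in (0, 1) for b in self.bits):
            raise SchemaError("fingerprint bits must be binary")

    def as_array(self) -> np.ndarray:
        return np.array(self.bits, dtype=float)


def _parse_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    # Re-parse the canonical form so atom ordering (and hence floating-point
    # summation order) is identical for every rewriting of the same molecule.
    return Chem.MolFromSmiles(Chem.MolToSmiles(mol))


def compute_descriptors(smiles: str) -> DescriptorSet:
    """Seven descriptors for one structure; deterministic per canonical form."""
    mol = _parse_smiles(smiles)
    mw = Descriptors.MolWt(mol)
    tpsa = Descriptors.TPSA(mol)
    logp = Crippen.MolLogP(mol)
    apol = 0.0
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        if symbol not in _POLARIZABILITY:
            raise StructureError(
                f"no polarizability value for element {symbol!r} in {smiles!r}"
            )
        apol += _POLARIZABILITY[symbol]
        apol += atom.GetTotalNumHs() * _POLARIZABILITY["H"]
    values = DescriptorSet(
        MW=float(mw),
        XLogP=float(logp),
        apol=float(apol),
        TopoPSA=float(tpsa),
        tpsaEfficiency=float(tpsa / mw) if mw > 0 else 0.0,
        ALogP=float(logp),
        AMR=float(Crippen.MolMR(mol)),
    )
    if not np.isfinite(values.as_array()).all():
        raise StructureError(f"non-finite descriptor for {smiles!r}")
    return values


def compute_estate_fingerprint(smiles: str) -> EStateFingerprint:
    """79-bit E-state atom-type presence fingerprint."""
    mol = _parse_smiles(smiles)
    counts, _sums = Fingerprinter.FingerprintMol(mol)
    return EStateFingerprint(bits=tuple(int(c > 0) for c in counts))


def featurize_drugs(
    drugs: list[DrugRecord],
) -> tuple[FeatureMatrix, list[str]]:
    """Per-drug descriptor + fingerprint matrix from SMILES.

    Drugs whose structure cannot be parsed or whose descriptors cannot be
    computed are excluded and returned in the second element (logged).
    """
    rows, ids, excluded = [], [], []
    for record in drugs:
        if not record.smiles:
            excluded.append(record.drug_id)
            continue
        try:
            desc = compute_descriptors(record.smiles)
            fp = compute_estate_fingerprint(record.smiles)
        except StructureError as exc:
            log.warning("drug %s excluded from molecular features: %s", record.drug_id, exc)
            excluded.append(record.drug_id)
            continue
        rows.append(np.concatenate([desc.as_array(), fp.as_array()]))
        ids.append(record.drug_id)
    if not rows:
        raise StructureError("no drug yielded molecular features")
    names = list(DESCRIPTOR_NAMES) + [f"estate_{b:02d}" for b in range(N_FP_BITS)]
    row_meta = pd.DataFrame(
        {"drug_id": ids, "cell_line": "-", "time_h": np.nan, "concentration": np.nan}
    )
    matrix = FeatureMatrix(
        row_meta,
        names,
        np.vstack(rows),
        {"descriptors": list(DESCRIPTOR_NAMES), "fingerprint": names[7:]},
    )
    return matrix, excluded


# --------------------------------------------------------------------------
# Transcriptional feature selection
# --------------------------------------------------------------------------

@dataclass
class SelectedFeatures:
    label: str
    method: str
    genes: list[str]
    scores: dict[str, float]


def cfs_merit(
    subset: tuple[int, ...], r_cf: np.ndarray, r_ff: np.ndarray
) -> float:
    """CFS merit k * mean|r_cf| / sqrt(k + k (k-1) mean|r_ff|) of a subset."""
    k = len(subset)
    if k == 0:
        return 0.0
    idx = list(subset)
    mean_cf = r_cf[idx].mean()
    if k == 1:
        return float(mean_cf)
    pairs = r_ff[np.ix_(idx, idx)]
    mean_ff = (pairs.sum() - k) / (k * (k - 1))  # exclude unit diagonal
    return float(k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff))


def _abs_corr_with_label(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|point-biserial| correlation of each column with a binary label."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = xc.std(axis=0)
    sy = yc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).mean(axis=0) / (sx * sy)
    return np.abs(np.nan_to_num(r))


def cfs_select(
    features: FeatureMatrix,
    label_column: np.ndarray,
    label_name: str = "",
    patience: int = 5,
    max_subset: int | None = None,
) -> SelectedFeatures:
    """Greedy best-first CFS over the transcriptional block.

    Expands the current best subset by single features, stopping after
    ``patience`` consecutive expansions without a merit improvement.  Equals
    exhaustive merit maximization on small feature counts (property-tested).
    """
    y = np.asarray(label_column, dtype=float)
    if len(np.unique(y)) < 2:
        raise SelectionError("label is constant; CFS undefined")
    names = (
        features.blocks.get("transcriptional", features.feature_names)
    )
    cols = [features.feature_names.index(n) for n in names]
    x = features.values[:, cols]
    if np.unique(y[: len(y)]).size < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise SelectionError("need at least 2 rows per class")
    r_cf = _abs_corr_with_label(x, y)
    r_ff = np.abs(np.corrcoef(x, rowvar=False))
    r_ff = np.nan_to_num(r_ff)
    p = len(names)
    max_subset = max_subset or p

    best_subset = (int(np.argmax(r_cf)),)
    best_merit = cfs_merit(best_subset, r_cf, r_ff)
    # max-heap of candidate subsets keyed by -merit
    heap: list[tuple[float, tuple[int, ...]]] = [(-best_merit, best_subset)]
    visited = {frozenset(best_subset)}
    stall = 0
    while heap and stall < patience:
        neg_merit, subset = heapq.heappop(heap)
        improved = False
        if len(subset) < max_subset:
            in_subset = set(subset)
            for j in range(p):
                if j in in_subset:
                    continue
                child = tuple(sorted(subset + (j,)))
                key = frozenset(child)
                if key in visited:
                    continue
                visited.add(key)
                merit = cfs_merit(child, r_cf, r_ff)
                if merit > -neg_merit:
                    heapq.heappush(heap, (-merit, child))
                if merit > best_merit:
                    best_merit, best_subset = merit, child
                    improved = True
        stall = 0 if improved else stall + 1
    selected = [names[j] for j in best_subset]
    return SelectedFeatures(
        label=label_name,
        method="cfs",
        genes=selected,
        scores={names[j]: float(r_cf[j]) for j in best_subset},
    )


def cfs_exhaustive(
    features: FeatureMatrix, label_column: np.ndarray, max_size: int | None = None
) -> tuple[list[str], float]:
    """Brute-force merit maximization; independent oracle for small toys."""
    y = np.asarray(label_column, dtype=float)
    names = features.blocks.get("transcriptional", features.feature_names)
    cols = [features.feature_names.index(n) for n in names]
    x = features.values[:, cols]
    r_cf = _abs_corr_with_label(x, y)
    r_ff = np.nan_to_num(np.abs(np.corrcoef(x, rowvar=False)))
    p = len(names)
    best, best_merit = (), -np.inf
    for size in range(1, (max_size or p) + 1):
        for subset in itertools.combinations(range(p), size):
            merit = cfs_merit(subset, r_cf, r_ff)
            if merit > best_merit:
                best, best_merit = subset, merit
    return [names[j] for j in best], float(best_merit)


def wrapper_select(
    features: FeatureMatrix,
    label_column: np.ndarray,
    n_iterations: int = 20,
    seed: int = 0,
    label_name: str = "",
    alpha: float = 0.05,
    n_estimators: int = 120,
    max_depth: int | None = 7,
    resolve_percentile: float = 100.0,
) -> SelectedFeatures:
    """Boruta-style shadow-feature wrapper selection.

    Each iteration appends an independently permuted shadow copy of every
    feature, fits a random forest, and scores a hit when a real feature's
    importance beats the maximum shadow importance.  Hits are tested against
    Binomial(n_iterations, 0.5) two-sided with Bonferroni correction across
    features; tentative features are resolved by comparing their median
    importance against the ``resolve_percentile`` of the per-iteration shadow
    maxima (default the maximum, which keeps the type-I rate near zero at the
    modest iteration counts used here).
    """
    y = np.asarray(label_column, dtype=int)
    if len(np.unique(y)) < 2:
        raise SelectionError("label is constant; wrapper selection undefined")
    names = features.blocks.get("transcriptional", features.feature_names)
    cols = [features.feature_names.index(n) for n in names]
    x = features.values[:, cols]
    p = len(names)
    rng = np.random.default_rng(seed)
    hits = np.zeros(p, dtype=int)
    importances = np.zeros((n_iterations, p))
    shadow_maxima = np.zeros(n_iterations)
    for it in range(n_iterations):
        shadow = np.column_stack([rng.permutation(x[:, j]) for j in range(p)])
        forest = RandomForestClassifier(
            n_estimators=n_estimators,
            max_depth=max_depth,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        ).fit(np.hstack([x, shadow]), y)
        imp = forest.feature_importances_
        shadow_max = imp[p:].max()
        hits += imp[:p] > shadow_max
        importances[it] = imp[:p]
        shadow_maxima[it] = shadow_max
    threshold = alpha / p  # Bonferroni
    confirmed, tentative = [], []
    for j in range(p):
        test = binomtest(int(hits[j]), n_iterations, 0.5, alternative="two-sided")
        if test.pvalue < threshold:
            if hits[j] > n_iterations / 2:
                confirmed.append(j)
        else:
            tentative.append(j)
    cutoff = float(np.percentile(shadow_maxima, resolve_percentile))
    resolved = [
        j for j in tentative if float(np.median(importances[:, j])) > cutoff
    ]
    if resolved:
        log.info("wrapper: %d tentative features resolved as confirmed", len(resolved))
    selected = sorted(confirmed + resolved)
    return SelectedFeatures(
        label=label_name,
        method="wrapper",
        genes=[names[j] for j in selected],
        scores={names[j]: float(np.median(importances[:, j])) for j in selected},
    )


# --------------------------------------------------------------------------
# Set agreement and pathway mapping
# --------------------------------------------------------------------------

def set_agreement(set_a: set, set_b: set, universe: set) -> KappaResult:
    """Cohen's Kappa of two sets encoded as membership vectors over a universe."""
    if len(universe) < 2:
        raise ValueError("universe must contain at least 2 elements")
    if not (set(set_a) <= set(universe) and set(set_b) <= set(universe)):
        raise ValueError("sets must be subsets of the universe")
    items = sorted(universe)
    a = np.array([1 if g in set_a else 0 for g in items])
    b = np.array([1 if g in set_b else 0 for g in items])
    return cohen_kappa(a, b)


def map_genes_to_pathways(
    genes: set[str], mapping: dict[str, set[str]]
) -> set[str]:
    """Union of pathway ids over mapped genes; unmapped genes logged."""
    pathways: set[str] = set()
    n_unmapped = 0
    for gene in genes:
        if gene in mapping:
            pathways |= mapping[gene]
        else:
            n_unmapped += 1
    if n_unmapped:
        log.info("%d of %d genes had no pathway annotation", n_unmapped, len(genes))
    return pathways


def union_selected_genes(selections: list[SelectedFeatures]) -> list[str]:
    """Deterministic union (sorted) of genes over labels and methods."""
    union: set[str] = set()
    for sel in selections:
        union |= set(sel.genes)
    return sorted(union)
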