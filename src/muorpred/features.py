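"""Molecular featurization: 2D descriptors, substructure counts, fingerprints.

All featurization is a pure function of the canonical molecule.  The
descriptor registry is the full RDKit 2D descriptor list (about 210 names,
depending on the RDKit release); feature filtering removes near-constant
and highly collinear columns, and model-based selection keeps a fraction
``alpha`` of the survivors ranked by impurity importance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import Descriptors, MACCSkeys
from rdkit.ML.Descriptors.MoleculeDescriptors import MolecularDescriptorCalculator
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import ExtraTreesClassifier

from muorpred.ligands import InvalidSmilesError, LigandDataset

# ---------------------------------------------------------------------------
# 2D descriptors

#: Registered descriptor names: the standard RDKit 2D set, minus Ipc whose
#: raw (non-log) value overflows to inf for large fused-ring systems.
DESCRIPTOR_NAMES: list[str] = [n for n, _ in Descriptors.descList if n != "Ipc"]

_CALCULATOR = MolecularDescriptorCalculator(DESCRIPTOR_NAMES)


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    return mol


# descriptors are a pure function of the SMILES text, so memoize per string
# (the pipeline featurizes the same pool molecules many times)
_DESCRIPTOR_CACHE: dict[str, np.ndarray] = {}


def _descriptor_row(smiles: str) -> np.ndarray:
    cached = _DESCRIPTOR_CACHE.get(smiles)
    if cached is None:
        # evaluate on the canonical form so atom input order cannot leak
        # into order-sensitive descriptors
        canonical = Chem.MolToSmiles(_mol(smiles))
        cached = _DESCRIPTOR_CACHE.get(canonical)
        if cached is None:
            mol = Chem.MolFromSmiles(canonical)
            cached = np.asarray(_CALCULATOR.CalcDescriptors(mol), dtype=float)
            if len(_DESCRIPTOR_CACHE) < 200_000:
                _DESCRIPTOR_CACHE[canonical] = cached
        if len(_DESCRIPTOR_CACHE) < 200_000:
            _DESCRIPTOR_CACHE[smiles] = cached
    return cached


def compute_descriptors(
    dataset: LigandDataset | Sequence[str],
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """2D descriptor table, one row per ligand (index = ligand id).

    Rows whose descriptor computation fails (non-finite values) are
    excluded; the excluded ids are stored in ``result.attrs["excluded"]``.
    """
    if isinstance(dataset, LigandDataset):
        smiles = dataset.smiles()
        ids = [r.id for r in dataset.records]
    else:
        smiles = list(dataset)
        ids = list(ids) if ids is not None else [f"mol{i}" for i in range(len(smiles))]
    rows, kept_ids, excluded = [], [], []
    for rid, smi in zip(ids, smiles, strict=True):
        try:
            values = _descriptor_row(smi)
        except InvalidSmilesError:
            excluded.append(rid)
            continue
        if not np.all(np.isfinite(values)):
            excluded.append(rid)
            continue
        rows.append(values)
        kept_ids.append(rid)
    table = pd.DataFrame(rows, index=kept_ids, columns=DESCRIPTOR_NAMES)
    table.attrs["excluded"] = excluded
    return table


# ---------------------------------------------------------------------------
# Substructure counts (the features the explainability analysis singles out)

#: Named SMARTS patterns.  ``aliphatic_heterocycles`` etc. are computed with
#: RDKit ring-descriptor routines rather than SMARTS (exact ring perception).
SMARTS_REGISTRY: dict[str, str] = {
    # hydroxyl on a non-carbonyl aliphatic carbon
    "aliphatic_oh": "[C!$(C=O);!$(C=S)][OX2H]",
    # tertiary amine ("XCCNR"): N with three carbon substituents, no H,
    # not amide/aromatic
    "tertiary_amine": "[NX3;H0;!$(N=*);!$(NC=O);!$(N(~O)~O);!n]([#6])([#6])[#6]",
    # aromatic 1,3-diazole ring
    "imidazole": "c1cncn1",
}

_RING_COUNTERS = {
    "aliphatic_heterocycles": Chem.rdMolDescriptors.CalcNumAliphaticHeterocycles,
    "aromatic_heterocycles": Chem.rdMolDescriptors.CalcNumAromaticHeterocycles,
    "aromatic_rings": Chem.rdMolDescriptors.CalcNumAromaticRings,
    "saturated_rings": Chem.rdMolDescriptors.CalcNumSaturatedRings,
}

SUBSTRUCTURE_NAMES = [
    "aliphatic_oh",
    "aliphatic_heterocycles",
    "aromatic_heterocycles",
    "tertiary_amine",
    "aromatic_rings",
    "saturated_rings",
    "imidazole",
]

_COMPILED = {name: Chem.MolFromSmarts(s) for name, s in SMARTS_REGISTRY.items()}


def count_substructures(smiles: str) -> dict[str, int]:
    """Counts of the named substructures/ring classes for one molecule.

    ``imidazole`` counts rings (symmetry-unique ring matches), the SMARTS
    patterns count unique atom-set matches.
    """
    mol = _mol(smiles)
    counts: dict[str, int] = {}
    for name in SUBSTRUCTURE_NAMES:
        if name in _RING_COUNTERS:
            counts[name] = int(_RING_COUNTERS[name](mol))
        elif name == "imidazole":
            matches = mol.GetSubstructMatches(_COMPILED[name], uniquify=True)
            rings = {frozenset(m) for m in matches}
            counts[name] = len(rings)
        else:
            counts[name] = len(mol.GetSubstructMatches(_COMPILED[name], uniquify=True))
    return counts


def substructure_table(smiles: Sequence[str], ids: Sequence[str] | None = None) -> pd.DataFrame:
    ids = list(ids) if ids is not None else [f"mol{i}" for i in range(len(smiles))]
    return pd.DataFrame(
        [count_substructures(s) for s in smiles], index=ids, columns=SUBSTRUCTURE_NAMES
    )


# ---------------------------------------------------------------------------
# Fingerprints and Tanimoto similarity

TOPOLOGICAL = "topological"
MACCS = "maccs"
MACCS_NBITS = 166  # public MACCS keys (bit 0 of RDKit's 167 is unused)


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary fingerprint with its kind tag."""

    kind: str
    bits: tuple[int, ...]  # sorted on-bit indices
    nbits: int

    def __len__(self) -> int:
        return self.nbits


def fingerprint(smiles: str, kind: str = TOPOLOGICAL, nbits: int = 2048) -> Fingerprint:
    """Path-based topological fingerprint (max path 7) or MACCS keys."""
    mol = _mol(smiles)
    if kind == TOPOLOGICAL:
        bv = Chem.RDKFingerprint(mol, maxPath=7, fpSize=nbits)
        return Fingerprint(kind, tuple(bv.GetOnBits()), nbits)
    if kind == MACCS:
        bv = MACCSkeys.GenMACCSKeys(mol)
        on = tuple(b - 1 for b in bv.GetOnBits() if b >= 1)
        return Fingerprint(kind, on, MACCS_NBITS)
    raise ValueError(f"unknown fingerprint kind {kind!r}")


def tanimoto_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """|a AND b| / |a OR b|; defined as 1.0 when both are all-zero."""
    if a.kind != b.kind or a.nbits != b.nbits:
        raise ValueError(
            f"fingerprint mismatch: {a.kind}/{a.nbits} vs {b.kind}/{b.nbits}"
        )
    sa, sb = set(a.bits), set(b.bits)
    union = len(sa | sb)
    if union == 0:
        return 1.0
    return len(sa & sb) / union


def tanimoto_distance_matrix(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Symmetric (1 - Tanimoto) distance matrix."""
    n = len(fps)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - tanimoto_similarity(fps[i], fps[j])
    return d


# ---------------------------------------------------------------------------
# Feature filtering and model-based selection

class FeatureFilter(BaseEstimator, TransformerMixin):
    """Drop near-constant and highly collinear descriptor columns.

    Near-zero variance: variance < ``var_threshold`` or the most frequent
    value occupying more than ``dominance`` of the rows.  Collinearity:
    columns are scanned in registry (input) order; for each pair with
    |Pearson r| > ``corr_threshold`` the *later* column is dropped.
    Idempotent: running the fitted filter's fit again on its own output is
    a no-op.

    Attributes
    ----------
    columns_ : list of surviving column names after fit.
    dropped_constant_, dropped_correlated_ : lists of removed names.
    """

    def __init__(
        self,
        corr_threshold: float = 0.9,
        var_threshold: float = 1e-8,
        dominance: float = 0.99,
    ):
        self.corr_threshold = corr_threshold
        self.var_threshold = var_threshold
        self.dominance = dominance

    def fit(self, X: pd.DataFrame, y=None) -> "FeatureFilter":
        if X.shape[1] == 0 or X.shape[0] == 0:
            raise ValueError("empty descriptor table")
        self.dropped_constant_ = []
        cols = []
        n = len(X)
        for c in X.columns:
            col = X[c].to_numpy()
            top_freq = pd.Series(col).value_counts(normalize=True).iloc[0]
            if np.var(col) < self.var_threshold or top_freq > self.dominance:
                self.dropped_constant_.append(c)
            else:
                cols.append(c)
        if not cols:
            raise ValueError("all columns removed by the variance filter")
        corr = np.corrcoef(X[cols].to_numpy(), rowvar=False)
        corr = np.atleast_2d(corr)
        keep: list[str] = []
        self.dropped_correlated_ = []
        kept_idx: list[int] = []
        for j, c in enumerate(cols):
            if any(abs(corr[j, i]) > self.corr_threshold for i in kept_idx):
                self.dropped_correlated_.append(c)
            else:
                keep.append(c)
                kept_idx.append(j)
        if not keep:
            raise ValueError("all columns removed by the correlation filter")
        self.columns_ = keep
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.columns_]


class ImportanceSelector(BaseEstimator, TransformerMixin):
    """Keep the top ``ceil(alpha * n_columns)`` features by forest importance.

    A small extra-trees forest (fixed seed) is fit on the training split
    only; columns are ranked by impurity importance (ties broken by input
    order).  ``alpha = 1`` is the identity.
    """

    def __init__(self, alpha: float = 1.0, n_estimators: int = 100, seed: int = 0):
        self.alpha = alpha
        self.n_estimators = n_estimators
        self.seed = seed

    def fit(self, X: pd.DataFrame, y) -> "ImportanceSelector":
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("feature selection requires two classes")
        k = math.ceil(self.alpha * X.shape[1])
        if self.alpha == 1:
            self.columns_ = list(X.columns)
            self.importances_ = None
            return self
        forest = ExtraTreesClassifier(
            n_estimators=self.n_estimators, random_state=self.seed, n_jobs=1
        )
        forest.fit(X.to_numpy(), y)
        imp = forest.feature_importances_
        order = np.lexsort((np.arange(len(imp)), -imp))
        chosen = sorted(order[:k])
        self.columns_ = [X.columns[i] for i in chosen]
        self.importances_ = pd.Series(imp, index=X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.columns_]


def filter_features(
    table: pd.DataFrame,
    corr_threshold: float = 0.9,
    var_threshold: float = 1e-8,
    dominance: float = 0.99,
) -> pd.DataFrame:
    """Functional wrapper over :class:`FeatureFilter`."""
    return FeatureFilter(corr_threshold, var_threshold, dominance).fit_transform(table)


def select_features(
    table: pd.DataFrame, labels, alpha: float, seed: int = 0
) -> pd.DataFrame:
    """Functional wrapper over :class:`ImportanceSelector`."""
    return ImportanceSelector(alpha=alpha, seed=seed).fit(table, labels).transform(table)
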