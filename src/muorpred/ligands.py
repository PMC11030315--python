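"""Ligand tables: SMILES canonicalization, Emax-rule labeling, deduplication.

A ligand record carries a SMILES string and either an author-stated
agonist/antagonist label or an Emax value measured in one of two reference
modes:

``damgo``
    Efficacy relative to the full agonist DAMGO (100%).  A compound is an
    agonist iff Emax > 10%.
``basal``
    Efficacy relative to basal (constitutive) activity (0%).  A compound is
    an agonist iff Emax > 14%; Emax <= 14% is antagonist (the cutoff is the
    low end of naltrexone's reported Emax range).

An author-stated label always takes precedence over the Emax rule.
Antagonists are the minority class throughout the package and are treated
as the positive class by the downstream models.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

AGONIST = "agonist"
ANTAGONIST = "antagonist"
UNLABELED = "unlabeled"

DAMGO = "damgo"
BASAL = "basal"
AUTHOR = "author"

#: Default Emax cutoffs (percent) for the two reference modes.
DAMGO_CUTOFF = 10.0
BASAL_CUTOFF = 14.0


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparsable SMILES: {smiles!r}")


class LabelingError(ValueError):
    """Raised when a record has neither an author label nor a usable Emax."""


def canonicalize_smiles(smiles: str, *, strip_salts: bool = True) -> str:
    """Return the canonical SMILES of ``smiles``.

    Idempotent: two SMILES of the same molecule map to the same output.
    Dot-separated salts/mixtures are reduced to the largest organic
    fragment (by heavy-atom count, carbon-containing fragments preferred)
    before canonicalization unless ``strip_salts`` is False.
    Stereochemistry is preserved.

    Raises
    ------
    InvalidSmilesError
        If the string does not parse.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise InvalidSmilesError(smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    if strip_salts and "." in smiles:
        frags = Chem.GetMolFrags(mol, asMols=True)
        if len(frags) > 1:
            def _key(m: Chem.Mol) -> tuple[int, int]:
                has_c = any(a.GetSymbol() == "C" for a in m.GetAtoms())
                return (int(has_c), m.GetNumHeavyAtoms())

            mol = max(frags, key=_key)
    return Chem.MolToSmiles(mol)


def strip_stereo(smiles: str) -> str:
    """Canonical SMILES with stereochemistry removed (for matching only)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class LigandRecord:
    """One molecule: SMILES, optional Emax + reference mode, optional label."""

    id: str
    smiles: str
    emax: float | None = None
    reference_mode: str | None = None  # damgo | basal | author
    label: str = UNLABELED  # agonist | antagonist | unlabeled
    source: str = ""

    def __post_init__(self) -> None:
        if self.label not in (AGONIST, ANTAGONIST, UNLABELED):
            raise ValueError(f"bad label {self.label!r}")
        if self.reference_mode not in (None, DAMGO, BASAL, AUTHOR):
            raise ValueError(f"bad reference mode {self.reference_mode!r}")
        if self.reference_mode == AUTHOR and self.label == UNLABELED:
            raise ValueError("author reference mode requires a label")


def assign_label(
    record: LigandRecord,
    damgo_cutoff: float = DAMGO_CUTOFF,
    basal_cutoff: float = BASAL_CUTOFF,
) -> str:
    """Agonist/antagonist label from author statement or the Emax rules.

    Author labels pass through unchanged.  Otherwise:
    DAMGO-referenced Emax > ``damgo_cutoff`` -> agonist (strict >);
    basal-referenced Emax > ``basal_cutoff`` -> agonist, <= -> antagonist.

    Raises
    ------
    LabelingError
        For an unlabeled record with no Emax or no reference mode.
    """
    if record.reference_mode == AUTHOR or (
        record.label != UNLABELED and record.reference_mode is None
    ):
        if record.label == UNLABELED:
            raise LabelingError(f"record {record.id}: author mode without label")
        return record.label
    if record.label != UNLABELED and record.emax is None:
        # explicit label without Emax: treat as author-stated
        return record.label
    if record.emax is None or record.reference_mode not in (DAMGO, BASAL):
        raise LabelingError(
            f"record {record.id}: no author label and no (emax, reference_mode)"
        )
    cutoff = damgo_cutoff if record.reference_mode == DAMGO else basal_cutoff
    return AGONIST if record.emax > cutoff else ANTAGONIST


@dataclass
class LigandDataset:
    """Ordered collection of ligand records with unique ids."""

    records: list[LigandRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = [i for i, c in Counter(ids).items() if c > 1]
            raise ValueError(f"duplicate ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LigandRecord]:
        return iter(self.records)

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(Counter(r.label for r in self.records))

    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def canonicalize(self, *, strip_salts: bool = True) -> "LigandDataset":
        """Canonical-SMILES copy; unparsable records are dropped."""
        out = []
        for r in self.records:
            try:
                out.append(replace(r, smiles=canonicalize_smiles(r.smiles, strip_salts=strip_salts)))
            except InvalidSmilesError:
                continue
        return LigandDataset(out)

    def labeled(
        self,
        damgo_cutoff: float = DAMGO_CUTOFF,
        basal_cutoff: float = BASAL_CUTOFF,
    ) -> "LigandDataset":
        """Copy with every record labeled through :func:`assign_label`."""
        return LigandDataset(
            [replace(r, label=assign_label(r, damgo_cutoff, basal_cutoff)) for r in self.records]
        )


def _match_key(record: LigandRecord, ignore_stereo: bool) -> str:
    return strip_stereo(record.smiles) if ignore_stereo else record.smiles


def deduplicate(
    dataset: LigandDataset, *, ignore_stereo: bool = False
) -> tuple[LigandDataset, list[tuple[LigandRecord, LigandRecord]]]:
    """Collapse records with identical canonical SMILES.

    Records must already be canonicalized.  Duplicates with identical labels
    keep the first occurrence; duplicates with contradictory labels are
    *both* excluded and reported as conflicts (fail-safe curation).

    Returns
    -------
    (deduplicated dataset, list of conflicting record pairs)
    """
    groups: dict[str, list[LigandRecord]] = {}
    order: list[str] = []
    for r in dataset.records:
        key = _match_key(r, ignore_stereo)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)

    kept: list[LigandRecord] = []
    conflicts: list[tuple[LigandRecord, LigandRecord]] = []
    for key in order:
        members = groups[key]
        labels = {m.label for m in members if m.label != UNLABELED}
        if len(labels) > 1:
            first_by_label = {}
            for m in members:
                first_by_label.setdefault(m.label, m)
            pair = sorted(first_by_label.values(), key=lambda m: m.id)
            conflicts.append((pair[0], pair[1]))
            continue
        kept.append(members[0])
    return LigandDataset(kept), conflicts


def remove_overlap(
    pool: LigandDataset, labeled: LigandDataset, *, ignore_stereo: bool = False
) -> LigandDataset:
    """Pool minus any canonical SMILES present in the labeled set."""
    seen = {_match_key(r, ignore_stereo) for r in labeled.records}
    return LigandDataset(
        [r for r in pool.records if _match_key(r, ignore_stereo) not in seen]
    )


# ---------------------------------------------------------------------------
# Table IO: CSV with header id,smiles,emax,reference_mode,label,source and
# plain .smi (SMILES + optional id per line) for unlabeled pools.

CSV_HEADER = ["id", "smiles", "emax", "reference_mode", "label", "source"]


def read_table(path: str | Path) -> LigandDataset:
    """Read a ligand CSV/TSV table (delimiter sniffed from the header line)."""
    path = Path(path)
    text = path.read_text()
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    records = []
    reader = csv.DictReader(text.splitlines(), delimiter=delim)
    for row in reader:
        emax = row.get("emax", "")
        records.append(
            LigandRecord(
                id=row["id"],
                smiles=row["smiles"],
                emax=float(emax) if emax not in ("", None) else None,
                reference_mode=row.get("reference_mode") or None,
                label=row.get("label") or UNLABELED,
                source=row.get("source", "") or "",
            )
        )
    return LigandDataset(records)


def write_table(dataset: LigandDataset, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for r in dataset.records:
            writer.writerow(
                [
                    r.id,
                    r.smiles,
                    "" if r.emax is None else repr(r.emax),
                    r.reference_mode or "",
                    "" if r.label == UNLABELED else r.label,
                    r.source,
                ]
            )


def read_smi(path: str | Path) -> LigandDataset:
    """Read a ``.smi`` file: one ``SMILES [id]`` per line, '#' comments."""
    records = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smiles = parts[0]
        rid = parts[1] if len(parts) > 1 else f"mol{i}"
        records.append(LigandRecord(id=rid, smiles=smiles))
    return LigandDataset(records)


def write_smi(dataset: LigandDataset, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for r in dataset.records:
            fh.write(f"{r.smiles} {r.id}\n")


def write_conflicts(
    conflicts: Sequence[tuple[LigandRecord, LigandRecord]], path: str | Path
) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["smiles", "id_a", "label_a", "id_b", "label_b"])
        for a, b in conflicts:
            writer.writerow([a.smiles, a.id, a.label, b.id, b.label])


def from_smiles(
    smiles: Iterable[str], labels: Iterable[str] | None = None, prefix: str = "mol"
) -> LigandDataset:
    """Convenience constructor from parallel SMILES/label sequences."""
    smiles = list(smiles)
    labels = list(labels) if labels is not None else [UNLABELED] * len(smiles)
    return LigandDataset(
        [
            LigandRecord(id=f"{prefix}{i}", smiles=s, label=lab)
            for i, (s, lab) in enumerate(zip(smiles, labels, strict=True))
        ]
    )
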