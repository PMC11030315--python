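"""Synthetic SMILES datasets with planted substructure-label structure.

The generator assembles molecules by decorating core scaffolds with
substituent fragments from a hand-curated library, then derives an Emax
value from a latent antagonist-propensity score computed from *actual*
substructure counts of the assembled molecule:

    a    = w_oh * N_AlOH + w_amine * N_XCCNR + w_aromhet * N_ArHc
           + w_imid * N_imd
    Emax = 100 * logistic(bias - a + eps),   eps ~ Normal(0, noise_sd)

so that aliphatic OH groups push toward antagonist (low Emax) and tertiary
amines / aromatic heterocycles / imidazoles push toward agonist — the
substructure-label correlations the explainability analysis reports for
the real data.  Labels are then derived from Emax through the real
labeling rules (DAMGO / basal reference modes), exercising the curation
module on every synthetic run.  Class counts are steered to the target
agonist:antagonist ratio (default 3.3:1) by rejection sampling.

The generator emulates: class imbalance, scaffold families, the planted
substructure-label correlations, both Emax reference modes, and a larger
unlabeled pool drawn from a broadened fragment distribution.  It does not
emulate pharmacological realism or real descriptor distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from rdkit import Chem

from muorpred.features import count_substructures, fingerprint, Fingerprint
from muorpred.ligands import (
    AGONIST,
    ANTAGONIST,
    BASAL,
    DAMGO,
    LigandDataset,
    LigandRecord,
    assign_label,
    canonicalize_smiles,
)
from muorpred.metrics import ConfusionCounts


@dataclass
class Substituent:
    name: str
    smiles: str
    tags: tuple[str, ...]


@dataclass
class Core:
    name: str
    template: str
    sites: int
    pool_only: bool = False


@dataclass
class FragmentLibrary:
    """Core scaffolds + tagged substituents; validated at build time."""

    cores: list[Core]
    substituents: list[Substituent]

    def validate(self) -> None:
        """Every core x substituent combination must parse."""
        for core in self.cores:
            for sub in self.substituents:
                smi = core.template.format(*([sub.smiles] * core.sites))
                if Chem.MolFromSmiles(smi) is None:
                    raise ValueError(
                        f"invalid combination {core.name} x {sub.name}: {smi}"
                    )


def load_fragment_library() -> FragmentLibrary:
    raw = json.loads(
        resources.files("muorpred.data").joinpath("fragments.json").read_text()
    )
    lib = FragmentLibrary(
        cores=[Core(c["name"], c["template"], c["sites"], c.get("pool_only", False))
               for c in raw["cores"]],
        substituents=[Substituent(s["name"], s["smiles"], tuple(s["tags"]))
                      for s in raw["substituents"]],
    )
    lib.validate()
    return lib


@dataclass
class SyntheticConfig:
    """Generator knobs.  Defaults are the study conditions the package's
    tests assume: 3.3:1 agonist:antagonist imbalance and a clearly planted
    substructure mechanism at moderate noise."""

    n_labeled: int = 1000
    n_unlabeled: int = 0
    ratio: float = 3.3  # agonist : antagonist
    w_oh: float = 1.0
    w_amine: float = -0.9
    w_aromhet: float = -0.7
    w_imid: float = -1.1
    bias: float = 0.0
    noise_sd: float = 0.3
    basal_fraction: float = 0.5  # share of records with basal-referenced Emax
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        if self.n_labeled < 4:
            raise ValueError("need at least 2 molecules per class")
        for w in (self.w_oh, self.w_amine, self.w_aromhet, self.w_imid):
            if not np.isfinite(w):
                raise ValueError("weights must be finite")


def _antagonist_propensity(counts: dict[str, int], cfg: SyntheticConfig) -> float:
    return (
        cfg.w_oh * counts["aliphatic_oh"]
        + cfg.w_amine * counts["tertiary_amine"]
        + cfg.w_aromhet * counts["aromatic_heterocycles"]
        + cfg.w_imid * counts["imidazole"]
    )


def _sample_molecule(
    rng: np.random.Generator,
    lib: FragmentLibrary,
    *,
    pool: bool = False,
    oh_boost: float = 2.0,
) -> str:
    """One decorated molecule; OH-bearing substituents are up-weighted so
    both classes are reachable at the 3.3:1 target ratio."""
    cores = [c for c in lib.cores if pool or not c.pool_only]
    core = cores[rng.integers(len(cores))]
    weights = np.array(
        [oh_boost if "oh" in s.tags else 1.0 for s in lib.substituents]
    )
    weights = weights / weights.sum()
    subs = [
        lib.substituents[i]
        for i in rng.choice(len(lib.substituents), size=core.sites, p=weights)
    ]
    smi = core.template.format(*[s.smiles for s in subs])
    return canonicalize_smiles(smi)


def generate_ligands(cfg: SyntheticConfig) -> tuple[LigandDataset, LigandDataset]:
    """Labeled dataset + unlabeled pool, deterministic given ``cfg.seed``.

    The labeled set hits the target class ratio exactly (by rejection);
    canonical SMILES are unique within and across the two outputs.

    Raises
    ------
    ValueError
        If the target ratio is infeasible at the requested size (the
        fragment space cannot supply enough unique molecules per class).
    """
    lib = load_fragment_library()
    rng = np.random.default_rng(cfg.seed)
    n_ag = int(round(cfg.n_labeled * cfg.ratio / (1.0 + cfg.ratio)))
    n_an = cfg.n_labeled - n_ag
    if min(n_ag, n_an) < 2:
        raise ValueError("infeasible ratio: fewer than 2 molecules in a class")
    seen: set[str] = set()
    ag_records: list[LigandRecord] = []
    an_records: list[LigandRecord] = []
    attempts, max_attempts = 0, 500 * cfg.n_labeled
    idx = 0
    while (len(ag_records) < n_ag or len(an_records) < n_an) and attempts < max_attempts:
        attempts += 1
        smi = _sample_molecule(rng, lib)
        if smi in seen:
            continue
        counts = count_substructures(smi)
        a = _antagonist_propensity(counts, cfg)
        eps = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
        s = cfg.bias - a + eps
        emax = 100.0 / (1.0 + np.exp(-s))
        mode = BASAL if rng.random() < cfg.basal_fraction else DAMGO
        record = LigandRecord(
            id=f"syn{idx}", smiles=smi, emax=float(emax), reference_mode=mode,
            source="synthetic",
        )
        label = assign_label(record)
        if label == AGONIST and len(ag_records) < n_ag:
            ag_records.append(record)
        elif label == ANTAGONIST and len(an_records) < n_an:
            an_records.append(record)
        else:
            continue
        seen.add(smi)
        idx += 1
    if len(ag_records) < n_ag or len(an_records) < n_an:
        raise ValueError(
            f"infeasible ratio at n={cfg.n_labeled}: got "
            f"{len(ag_records)} agonists / {len(an_records)} antagonists"
        )
    records = sorted(ag_records + an_records, key=lambda r: int(r.id[3:]))
    labeled = LigandDataset(records).labeled()
    pool_records: list[LigandRecord] = []
    attempts = 0
    while len(pool_records) < cfg.n_unlabeled and attempts < 500 * max(1, cfg.n_unlabeled):
        attempts += 1
        smi = _sample_molecule(rng, lib, pool=True, oh_boost=1.0)
        if smi in seen:
            continue
        seen.add(smi)
        pool_records.append(
            LigandRecord(id=f"pool{len(pool_records)}", smiles=smi, source="synthetic-pool")
        )
    if len(pool_records) < cfg.n_unlabeled:
        raise ValueError("fragment space exhausted while drawing the unlabeled pool")
    return labeled, LigandDataset(pool_records)


def generate_confusion_fixture(
    tag: int, tan: int, fag: int, fan: int
) -> tuple[list[str], list[str]]:
    """Label/prediction vectors realizing exactly the requested counts.

    Agonist = negative class, antagonist = positive class; TAG true
    agonists, TAN true antagonists, FAG antagonists predicted agonist,
    FAN agonists predicted antagonist.
    """
    ConfusionCounts(tag, tan, fag, fan)  # validates non-negativity
    truth = (
        [AGONIST] * tag + [AGONIST] * fan + [ANTAGONIST] * tan + [ANTAGONIST] * fag
    )
    pred = (
        [AGONIST] * tag + [ANTAGONIST] * fan + [ANTAGONIST] * tan + [AGONIST] * fag
    )
    return truth, pred


def plant_cluster_structure(
    n_families: int = 3,
    family_size: int = 5,
    seed: int = 0,
    fingerprint_kind: str = "topological",
    cutoff: float = 0.7,
) -> tuple[list[str], list[Fingerprint], list[int]]:
    """Scaffold families whose within-family Tanimoto distance is below the
    cutoff and between-family distance above it.

    Families are homologous series on distinct cores (members differ by
    small alkyl/halogen substituents).  The planted separation is verified
    before returning; a violation raises, so the returned partition is a
    true ground truth by construction.

    Returns (smiles, fingerprints, family index per molecule).
    """
    if n_families < 1:
        raise ValueError("need at least one family")
    lib = load_fragment_library()
    from muorpred.features import tanimoto_similarity

    # large, mutually distinctive cores keep within-family similarity high
    # and between-family similarity low for path fingerprints
    core_names = ["quinoline", "biphenyl", "morpholine", "tetralin", "naphthalene"]
    if n_families > len(core_names):
        raise ValueError("not enough distinct cores for that many families")
    small = ["[H]", "C", "F", "Cl", "OC", "CC"]
    cores = {c.name: c for c in lib.cores}
    smiles, family = [], []
    for f in range(n_families):
        core = cores[core_names[f]]
        for m in range(family_size):
            subs = [small[(m + k) % len(small)] for k in range(core.sites)]
            smiles.append(canonicalize_smiles(core.template.format(*subs)))
            family.append(f)
    fps = [fingerprint(s, fingerprint_kind) for s in smiles]
    for i in range(len(fps)):
        for j in range(i + 1, len(fps)):
            d = 1.0 - tanimoto_similarity(fps[i], fps[j])
            if family[i] == family[j] and d >= cutoff:
                raise ValueError(
                    f"planted structure violated: within-family distance {d:.2f}"
                )
            if family[i] != family[j] and d <= cutoff:
                raise ValueError(
                    f"planted structure violated: between-family distance {d:.2f}"
                )
    return smiles, fps, family
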