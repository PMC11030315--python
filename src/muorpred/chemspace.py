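"""Chemical-space analysis: Tanimoto clustering, centroids, scaffold classes.

The dataset is clustered by hierarchical agglomerative clustering on the
(1 - Tanimoto similarity) distance matrix, cut at a fixed distance (default
0.7).  Complete linkage is the default so that every within-cluster pair is
within the cutoff.  Clusters are renumbered 1, 2, ... by decreasing size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem
from sklearn.base import BaseEstimator
from sklearn.cluster import AgglomerativeClustering

from muorpred.features import Fingerprint, tanimoto_distance_matrix, tanimoto_similarity
from muorpred.ligands import ANTAGONIST, InvalidSmilesError

PHENANTHRENE = "phenanthrene"
BENZOMORPHAN = "benzomorphan"
PHENYLPIPERIDINE = "phenylpiperidine"
DIPHENYLHEPTANE = "diphenylheptane"
PHENYLPROPYLAMINE = "phenylpropylamine"
OTHER = "other"

#: Precedence-ordered scaffold SMARTS.  Fused opioid cores overlap (a
#: benzomorphan contains a piperidine), so the more specific core is tried
#: first; each class matches if ANY of its patterns matches.  The patterns
#: are pragmatic approximations of the five classical opioid chemotypes,
#: written bond-order-agnostic (``~``) where the cores occur both aromatic
#: and partially saturated.
SCAFFOLD_SMARTS: list[tuple[str, list[str]]] = [
    (
        PHENANTHRENE,
        # angularly fused 6-6-6 carbocycle (morphinan A-B-C ring system,
        # phenanthrene itself, oripavines)
        [
            "[#6]~1~[#6]~[#6]~[#6]~2~[#6](~[#6]~1)~[#6]~[#6]~[#6]~1~[#6]~2~[#6]~[#6]~[#6]~[#6]~1",
        ],
    ),
    (
        BENZOMORPHAN,
        # 2,6-methano-3-benzazocine core (pentazocine, ketocyclazocine);
        # also contained in morphinans, which the phenanthrene precedence
        # claims first
        ["[#6]1[#6]2[#6]c3ccccc3[#6]1[#6][#6][#7]2"],
    ),
    (
        PHENYLPIPERIDINE,
        # piperidine with an aryl at C4 (meperidine), via an anilide N
        # (fentanyl) or N-phenethyl; 4-anilidopiperidines included
        [
            "c1ccccc1[C;R]1[C;R][C;R][N;R][C;R][C;R]1",
            "c1ccccc1[NX3][C;R]1[C;R][C;R][N;R][C;R][C;R]1",
            "c1ccccc1[CX4][C;R]1[C;R][C;R][N;R][C;R][C;R]1",
            "c1ccccc1[CX4][CX4][N;R]1[C;R][C;R][C;R][C;R][C;R]1",
        ],
    ),
    (
        DIPHENYLHEPTANE,
        # acyclic carbon bearing two phenyl rings (methadone, propoxyphene)
        ["[CX4;!R](c1ccccc1)c1ccccc1"],
    ),
    (
        PHENYLPROPYLAMINE,
        # aryl-C-C-C-N chain (tramadol, tapentadol)
        ["c1ccccc1[CX4][CX4][CX4][NX3]"],
    ),
]

_COMPILED_SCAFFOLDS = [
    (name, [Chem.MolFromSmarts(s) for s in pats]) for name, pats in SCAFFOLD_SMARTS
]

SCAFFOLD_CLASSES = [name for name, _ in SCAFFOLD_SMARTS] + [OTHER]


def assign_scaffold_class(smiles: str) -> str:
    """First matching scaffold class in precedence order, else ``other``."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    for name, patterns in _COMPILED_SCAFFOLDS:
        if any(mol.HasSubstructMatch(p) for p in patterns):
            return name
    return OTHER


@dataclass
class ClusterAssignment:
    """Partition of the dataset with per-cluster summaries.

    Cluster ids are 1-based and ordered by decreasing cluster size (ties
    broken by the smallest member index).
    """

    cluster_ids: list[int]  # per ligand, parallel to the input order
    sizes: dict[int, int]
    members: dict[int, list[int]]  # cluster id -> member indices

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


class TanimotoClustering(BaseEstimator):
    """Agglomerative clustering on 1 - Tanimoto distance, cut at a cutoff.

    Parameters
    ----------
    distance_cutoff : float in [0, 1], default 0.7
        Clusters are formed by cutting the dendrogram at this distance.
    linkage : {"complete", "average", "single"}, default "complete"

    Attributes
    ----------
    assignment_ : ClusterAssignment
    labels_ : np.ndarray of 1-based cluster ids, per input fingerprint.
    """

    def __init__(self, distance_cutoff: float = 0.7, linkage: str = "complete"):
        self.distance_cutoff = distance_cutoff
        self.linkage = linkage

    def fit(self, fingerprints: Sequence[Fingerprint], y=None) -> "TanimotoClustering":
        if len(fingerprints) == 0:
            raise ValueError("no fingerprints to cluster")
        if len(fingerprints) == 1:
            raw = np.array([0])
        else:
            dist = tanimoto_distance_matrix(fingerprints)
            model = AgglomerativeClustering(
                n_clusters=None,
                metric="precomputed",
                linkage=self.linkage,
                distance_threshold=self.distance_cutoff,
            )
            raw = model.fit_predict(dist)
        self.assignment_ = _renumber(raw)
        self.labels_ = np.asarray(self.assignment_.cluster_ids)
        return self

    def fit_predict(self, fingerprints: Sequence[Fingerprint], y=None) -> np.ndarray:
        return self.fit(fingerprints).labels_


def _renumber(raw_labels: np.ndarray) -> ClusterAssignment:
    members_raw: dict[int, list[int]] = {}
    for i, lab in enumerate(raw_labels):
        members_raw.setdefault(int(lab), []).append(i)
    ordered = sorted(members_raw.values(), key=lambda m: (-len(m), m[0]))
    cluster_ids = [0] * len(raw_labels)
    sizes, members = {}, {}
    for new_id, mem in enumerate(ordered, start=1):
        sizes[new_id] = len(mem)
        members[new_id] = mem
        for i in mem:
            cluster_ids[i] = new_id
    return ClusterAssignment(cluster_ids, sizes, members)


def cluster(
    fingerprints: Sequence[Fingerprint],
    distance_cutoff: float = 0.7,
    linkage: str = "complete",
) -> ClusterAssignment:
    """Functional wrapper over :class:`TanimotoClustering`."""
    return TanimotoClustering(distance_cutoff, linkage).fit(fingerprints).assignment_


def centroid(
    member_indices: Sequence[int],
    fingerprints: Sequence[Fingerprint],
    ids: Sequence[str] | None = None,
) -> str | int:
    """Most representative member: maximal mean Tanimoto similarity to the
    cluster (including self); ties broken by smallest ligand id."""
    if len(member_indices) == 0:
        raise ValueError("empty cluster")
    ids = list(ids) if ids is not None else list(range(len(fingerprints)))
    best = None
    for i in member_indices:
        mean_sim = float(
            np.mean([tanimoto_similarity(fingerprints[i], fingerprints[j]) for j in member_indices])
        )
        key = (-mean_sim, str(ids[i]))
        if best is None or key < best[0]:
            best = (key, ids[i])
    return best[1]


def antagonist_fraction(member_indices: Sequence[int], labels: Sequence[str]) -> float:
    """Percentage of antagonists among cluster members."""
    if len(member_indices) == 0:
        raise ValueError("empty cluster")
    from muorpred.ligands import UNLABELED

    for i in member_indices:
        if labels[i] == UNLABELED:
            raise ValueError(f"member {i} is unlabeled")
    n_an = sum(1 for i in member_indices if labels[i] == ANTAGONIST)
    return 100.0 * n_an / len(member_indices)


def nearest_cross_class(
    index: int,
    labels: Sequence[str],
    fingerprints: Sequence[Fingerprint],
    ids: Sequence[str] | None = None,
) -> str | int:
    """Opposite-class ligand with the highest Tanimoto similarity to
    ``index``; ties broken by smallest id."""
    ids = list(ids) if ids is not None else list(range(len(fingerprints)))
    own = labels[index]
    best = None
    for j in range(len(fingerprints)):
        if j == index or labels[j] == own:
            continue
        sim = tanimoto_similarity(fingerprints[index], fingerprints[j])
        key = (-sim, str(ids[j]))
        if best is None or key < best[0]:
            best = (key, ids[j])
    if best is None:
        raise ValueError("no opposite-class ligand in the dataset")
    return best[1]


def cluster_summary(
    assignment: ClusterAssignment,
    fingerprints: Sequence[Fingerprint],
    labels: Sequence[str],
    ids: Sequence[str] | None = None,
):
    """Per-cluster table: id, size, antagonist %, centroid ligand id."""
    import pandas as pd

    ids = list(ids) if ids is not None else list(range(len(fingerprints)))
    rows = []
    for cid in sorted(assignment.sizes):
        mem = assignment.members[cid]
        rows.append(
            {
                "cluster_id": cid,
                "size": assignment.sizes[cid],
                "antagonist_pct": antagonist_fraction(mem, labels),
                "centroid_id": centroid(mem, fingerprints, ids),
            }
        )
    return pd.DataFrame(rows)
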