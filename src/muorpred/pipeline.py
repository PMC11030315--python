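"""End-to-end orchestration: curate -> featurize -> cluster -> train -> evaluate.

Every run is driven by a :class:`RunConfig`; all randomness flows from its
single ``seed``.  Artifacts are written into a run directory together with
a manifest (config digest + seeds), so a rerun with the same config
reproduces all deterministic outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from muorpred import ligands as lig
from muorpred.chemspace import TanimotoClustering, assign_scaffold_class, cluster_summary
from muorpred.dmpnn import DMPNNEnsemble
from muorpred.features import fingerprint
from muorpred.metrics import (
    MetricsReport,
    compute_metrics,
    confusion,
    evaluate_scores,
)
from muorpred.sampling import stratified_split
from muorpred.trees import DescriptorPipelineClassifier
from muorpred.ligands import AGONIST, ANTAGONIST


@dataclass
class RunConfig:
    """Configuration for :func:`run_pipeline`.

    ``reference_scale`` restores the printed protocol (9:1 split with 9-fold
    trees / 10-fold graph CV, 1000-iteration random search); the default is
    desk scale, which finishes in minutes on one CPU.
    """

    seed: int = 0
    damgo_cutoff: float = 10.0
    basal_cutoff: float = 14.0
    ignore_stereo: bool = False
    test_fraction: float = 0.1
    cluster_cutoff: float = 0.7
    fingerprint_kind: str = "topological"
    tree_kind: str = "et"
    alpha: float = 1.0
    use_smote: bool = True
    search_iterations: int = 0
    tree_folds: int = 9
    mpnn_folds: int = 0  # 0 disables the graph model
    run_chemspace: bool = True
    run_trees: bool = True
    reference_scale: bool = False

    def __post_init__(self) -> None:
        if self.reference_scale:
            self.search_iterations = 1000
            self.tree_folds = 9
            if self.mpnn_folds:
                self.mpnn_folds = 10

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def curate(
    dataset: lig.LigandDataset, config: RunConfig | None = None
) -> tuple[lig.LigandDataset, list]:
    """Canonicalize, label, and deduplicate a raw ligand table."""
    config = config or RunConfig()
    canonical = dataset.canonicalize()
    labeled = canonical.labeled(config.damgo_cutoff, config.basal_cutoff)
    return lig.deduplicate(labeled, ignore_stereo=config.ignore_stereo)


def run_pipeline(
    dataset: lig.LigandDataset,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute the configured stages; returns (and optionally writes) results.

    Stages: curation -> fingerprints/chemspace -> stratified split ->
    tree and/or graph-model training (SMOTE inside) -> F1-optimal
    thresholding -> hold-out evaluation.
    """
    config = config or RunConfig()
    results: dict = {"config_digest": config.digest(), "seed": config.seed}
    curated, conflicts = curate(dataset, config)
    results["n_records"] = len(curated)
    results["class_counts"] = curated.class_counts
    results["n_conflicts"] = len(conflicts)

    smiles = curated.smiles()
    labels = curated.labels()
    if config.run_chemspace:
        fps = [fingerprint(s, config.fingerprint_kind) for s in smiles]
        clustering = TanimotoClustering(config.cluster_cutoff).fit(fps)
        summary = cluster_summary(
            clustering.assignment_, fps, labels, [r.id for r in curated]
        )
        results["n_clusters"] = clustering.assignment_.n_clusters
        results["cluster_summary"] = summary
        results["scaffold_classes"] = pd.Series(
            [assign_scaffold_class(s) for s in smiles]
        ).value_counts().to_dict()

    y = np.array([1 if l == ANTAGONIST else 0 for l in labels])
    if config.run_trees or config.mpnn_folds:
        split = stratified_split(
            range(len(smiles)), y, config.test_fraction, seed=config.seed
        )
        tr = np.array(split.train_ids, dtype=int)
        te = np.array(split.test_ids, dtype=int)
        assert not set(tr) & set(te), "train/test overlap"
        results["split"] = {"n_train": len(tr), "n_test": len(te)}
        train_smiles = [smiles[i] for i in tr]
        test_smiles = [smiles[i] for i in te]
        if config.run_trees:
            clf = DescriptorPipelineClassifier(
                kind=config.tree_kind,
                alpha=config.alpha,
                use_smote=config.use_smote,
                folds=config.tree_folds,
                search_iterations=config.search_iterations,
                seed=config.seed,
            ).fit(train_smiles, y[tr])
            scores = clf.predict_proba(test_smiles)[:, 1]
            results["tree_metrics"] = evaluate_scores(
                scores, y[te], threshold=clf.threshold_
            )
            results["tree_model"] = clf
        if config.mpnn_folds:
            ens = DMPNNEnsemble(k=config.mpnn_folds, seed=config.seed).fit(
                train_smiles, y[tr]
            )
            scores = ens.predict_proba(test_smiles)[:, 1]
            results["mpnn_metrics"] = evaluate_scores(
                scores, y[te], threshold=ens.threshold_
            )
            results["mpnn_model"] = ens

    if out_dir is not None:
        _write_artifacts(results, curated, conflicts, Path(out_dir))
    return results


def _write_artifacts(results: dict, curated, conflicts, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    lig.write_table(curated, out_dir / "curated.csv")
    lig.write_conflicts(conflicts, out_dir / "conflicts.csv")
    if "cluster_summary" in results:
        results["cluster_summary"].to_csv(out_dir / "clusters.csv", index=False)
    manifest = {
        k: v
        for k, v in results.items()
        if isinstance(v, (int, float, str, dict)) and k != "cluster_summary"
    }
    for key in ("tree_metrics", "mpnn_metrics"):
        if key in results:
            manifest[key] = results[key].rounded()
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def external_validate(
    model,
    external: lig.LigandDataset,
    training_smiles: Sequence[str] | None = None,
) -> tuple[MetricsReport, pd.DataFrame]:
    """Apply a fitted model to an external labeled set.

    Raises on any overlap between external and training molecules
    (leakage guard).  Returns the metrics report and per-compound
    predictions.
    """
    if len(external) == 0:
        raise ValueError("empty external set")
    ext_smiles = external.smiles()
    if training_smiles is not None:
        overlap = set(ext_smiles) & set(training_smiles)
        if overlap:
            raise ValueError(f"external set overlaps training: {sorted(overlap)[:3]}")
    y = np.array([1 if l == ANTAGONIST else 0 for l in external.labels()])
    probs = model.predict_proba(ext_smiles)[:, 1]
    thr = getattr(model, "threshold_", 0.5)
    pred = (probs >= thr).astype(int)
    c = confusion(y, pred)
    report = compute_metrics(c)
    report.threshold = float(thr)
    if len(np.unique(y)) == 2:
        from muorpred.metrics import auc

        report.auc = 100.0 * auc(probs, y)
    table = pd.DataFrame(
        {
            "id": [r.id for r in external],
            "smiles": ext_smiles,
            "probability": probs,
            "predicted": [ANTAGONIST if p else AGONIST for p in pred],
            "true": external.labels(),
        }
    )
    return report, table
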