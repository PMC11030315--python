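"""Evaluation metrics for the agonist/antagonist classifiers.

Antagonists (the minority class) are the positive class.  With TAG, TAN,
FAG, FAN the numbers of true agonists, true antagonists, false agonists
(antagonists predicted agonist) and false antagonists (agonists predicted
antagonist):

    Recall(AG) = TAG / (TAG + FAN)      Prec(AG) = TAG / (TAG + FAG)
    Recall(AN) = TAN / (TAN + FAG)      Prec(AN) = TAN / (TAN + FAN)
    BA         = (Recall(AG) + Recall(AN)) / 2
    F1(AN)     = 2 Recall(AN) Prec(AN) / (Recall(AN) + Prec(AN))

All metrics are reported in percent.  The classification probability
threshold is optimized to maximize F1(AN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from muorpred.ligands import AGONIST, ANTAGONIST

METRIC_NAMES = ["recall_ag", "recall_an", "prec_ag", "prec_an", "ba", "f1_an", "auc"]


@dataclass(frozen=True)
class ConfusionCounts:
    """TAG / TAN / FAG / FAN counts (antagonist = positive class)."""

    tag: int
    tan: int
    fag: int
    fan: int

    def __post_init__(self) -> None:
        if min(self.tag, self.tan, self.fag, self.fan) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tag + self.tan + self.fag + self.fan

    @property
    def n_agonists(self) -> int:
        """Number of true-agonist samples (TAG + FAN)."""
        return self.tag + self.fan

    @property
    def n_antagonists(self) -> int:
        """Number of true-antagonist samples (TAN + FAG)."""
        return self.tan + self.fag


def _as_binary(labels: Sequence) -> np.ndarray:
    """Map labels to 1 = antagonist (positive), 0 = agonist."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "SUO":
        out = np.empty(len(arr), dtype=int)
        for i, v in enumerate(arr):
            if v == ANTAGONIST:
                out[i] = 1
            elif v == AGONIST:
                out[i] = 0
            else:
                raise ValueError(f"non-binary label {v!r}")
        return out
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1, True, False}:
        raise ValueError(f"non-binary labels {sorted(uniq)!r}")
    return arr.astype(int)


def confusion(true_labels: Sequence, predicted_labels: Sequence) -> ConfusionCounts:
    """Tally TAG/TAN/FAG/FAN from parallel label vectors."""
    t = _as_binary(true_labels)
    p = _as_binary(predicted_labels)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} vs {len(p)}")
    return ConfusionCounts(
        tag=int(np.sum((t == 0) & (p == 0))),
        tan=int(np.sum((t == 1) & (p == 1))),
        fag=int(np.sum((t == 1) & (p == 0))),
        fan=int(np.sum((t == 0) & (p == 1))),
    )


@dataclass
class MetricsReport:
    """Per-class recalls/precisions, BA, F1(AN), optional AUC — in percent.

    Metrics whose denominator is zero are absent (None), never silently 0.
    """

    recall_ag: float | None = None
    recall_an: float | None = None
    prec_ag: float | None = None
    prec_an: float | None = None
    ba: float | None = None
    f1_an: float | None = None
    auc: float | None = None
    threshold: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def rounded(self, ndigits: int = 1) -> dict[str, float | None]:
        """Report-style rounding (one decimal in percent by default)."""
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in self.as_dict().items()
        }


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Per-class recall/precision, BA and F1(AN) from confusion counts."""

    def ratio(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    recall_ag = ratio(c.tag, c.tag + c.fan)
    recall_an = ratio(c.tan, c.tan + c.fag)
    prec_ag = ratio(c.tag, c.tag + c.fag)
    prec_an = ratio(c.tan, c.tan + c.fan)
    ba = None
    if recall_ag is not None and recall_an is not None:
        ba = (recall_ag + recall_an) / 2.0
    f1_an = None
    if recall_an is not None and prec_an is not None and (recall_an + prec_an) > 0:
        f1_an = 2.0 * recall_an * prec_an / (recall_an + prec_an)
    return MetricsReport(
        recall_ag=recall_ag,
        recall_an=recall_an,
        prec_ag=prec_ag,
        prec_an=prec_an,
        ba=ba,
        f1_an=f1_an,
    )


def auc(scores: Sequence[float], true_labels: Sequence) -> float:
    """Rank-based ROC AUC: probability a random antagonist outscores a
    random agonist, ties counted 1/2.  Invariant under monotone transforms
    of the scores."""
    t = _as_binary(true_labels)
    if len(np.unique(t)) < 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(t, np.asarray(scores, dtype=float)))


def f1_at_threshold(scores: np.ndarray, t_bin: np.ndarray, thr: float) -> float:
    """F1(AN) fraction at a hard threshold (>= thr -> antagonist)."""
    pred = (scores >= thr).astype(int)
    c = confusion(t_bin, pred)
    rep = compute_metrics(c)
    return 0.0 if rep.f1_an is None else rep.f1_an / 100.0


def optimize_threshold(scores: Sequence[float], true_labels: Sequence) -> float:
    """Threshold (on antagonist probability) maximizing F1(AN).

    Candidates are the midpoints between adjacent distinct sorted scores,
    plus the 0.5 fallback; ties are broken toward the candidate closest to
    0.5.  The degenerate "call everything antagonist" threshold below the
    minimum score is deliberately not a candidate.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no scores")
    t = _as_binary(true_labels)
    uniq = np.unique(scores)
    candidates = list((uniq[:-1] + uniq[1:]) / 2.0) + [0.5]
    best_thr, best_key = None, None
    for thr in candidates:
        f1 = f1_at_threshold(scores, t, thr)
        key = (-f1, abs(thr - 0.5))
        if best_key is None or key < best_key:
            best_key, best_thr = key, thr
    return float(best_thr)


def aggregate_runs(reports: Sequence[MetricsReport]) -> dict[str, dict[str, float]]:
    """Per-metric mean and sample SD over repeated runs.

    Absent values are skipped; the contributing run count is reported per
    metric as ``n``.
    """
    if len(reports) < 2:
        raise ValueError("aggregation needs at least 2 reports")
    out: dict[str, dict[str, float]] = {}
    for name in METRIC_NAMES:
        values = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        if not values:
            continue
        arr = np.asarray(values, dtype=float)
        out[name] = {
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "n": len(arr),
        }
    return out


def evaluate_scores(
    scores: Sequence[float],
    true_labels: Sequence,
    threshold: float | None = None,
) -> MetricsReport:
    """Full report from probabilities: AUC plus thresholded class metrics.

    If ``threshold`` is None it is optimized on these scores (training or
    validation data only — never on a hold-out set being reported)."""
    scores = np.asarray(scores, dtype=float)
    t = _as_binary(true_labels)
    if threshold is None:
        threshold = optimize_threshold(scores, t)
    c = confusion(t, (scores >= threshold).astype(int))
    rep = compute_metrics(c)
    rep.threshold = float(threshold)
    if len(np.unique(t)) == 2:
        rep.auc = 100.0 * auc(scores, t)
    return rep
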