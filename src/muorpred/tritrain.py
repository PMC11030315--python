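"""Tri-training with disagreement over three heterogeneous classifiers.

Three learners (typically gradient boosted trees, extra trees, and a
directed MPNN) are first trained on the labeled split.  Each iteration:

1. every learner predicts a hard label for every pool item (at its own
   F1-optimal threshold);
2. items on which all three agree are *discarded for this round*; items on
   which exactly one learner dissents are appended, with the majority
   label, to the dissenter's training set (with binary labels these two
   cases are exhaustive — a two-way dissent is impossible);
3. all three learners are retrained from scratch on their augmented sets
   and evaluated on the untouched hold-out set;
4. the next iteration consumes the previously discarded items.

The loop stops when the pool is depleted, nothing was routed (zero
disagreement), the best hold-out AUC fails to improve by ``min_auc_gain``
over a full iteration, or ``max_iterations`` is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from muorpred.metrics import auc as roc_auc

LEARNER_NAMES = ("A", "B", "C")


@dataclass
class StoppingRule:
    """Termination policy for the tri-training loop."""

    max_iterations: int = 5
    min_auc_gain: float = 0.001
    stop_on_depletion: bool = True
    stop_on_agreement: bool = True

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class PseudoLabeled:
    """A pool item adopted into a learner's training set, with provenance."""

    smiles: str
    label: int
    iteration: int
    teachers: tuple[str, str]


@dataclass
class TriTrainState:
    """Training sets, pool, discards and per-iteration history."""

    labeled_smiles: list[str]
    labeled_y: np.ndarray
    additions: dict[str, list[PseudoLabeled]]
    pool: list[str]
    discarded: list[str]
    iteration: int
    history: list[dict]  # one row per (iteration, learner)

    def training_size(self, learner: str) -> int:
        return len(self.labeled_smiles) + len(self.additions[learner])


def disagreement_route(
    pred_a: Sequence[int],
    pred_b: Sequence[int],
    pred_c: Sequence[int],
    pool: Sequence[str],
) -> tuple[list[tuple[str, int]], list[tuple[str, int]], list[tuple[str, int]], list[str]]:
    """Route pool items by the disagreement rule.

    Returns (additions_A, additions_B, additions_C, discarded) where each
    addition is ``(item, majority_label)``.  Unanimous items are discarded.
    """
    preds = [np.asarray(p) for p in (pred_a, pred_b, pred_c)]
    for p in preds:
        if len(p) != len(pool):
            raise ValueError("prediction/pool length mismatch")
        if not set(np.unique(p)).issubset({0, 1}):
            raise ValueError("tri-training requires binary (0/1) labels")
    additions: list[list[tuple[str, int]]] = [[], [], []]
    discarded: list[str] = []
    for i, item in enumerate(pool):
        votes = [int(p[i]) for p in preds]
        total = sum(votes)
        if total in (0, 3):
            discarded.append(item)
            continue
        majority = 1 if total == 2 else 0
        dissenter = votes.index(1 - majority)
        # with binary labels exactly one learner dissents here
        assert votes.count(1 - majority) == 1
        additions[dissenter].append((item, majority))
    return additions[0], additions[1], additions[2], discarded


class TriTraining:
    """Orchestrator for tri-training with disagreement.

    Parameters
    ----------
    learner_factories : mapping name -> callable(seed) -> estimator
        Each estimator must implement ``fit(smiles, y)`` and
        ``predict_proba(smiles) -> (n, 2)``; a fitted ``threshold_``
        attribute is used for hard teacher labels (0.5 otherwise, or force
        it with ``threshold=0.5``).
    stopping : StoppingRule
    threshold : float or None
        None (default) uses each learner's own optimized threshold.
    seed : int
        Per-iteration learner seeds are derived deterministically from
        (seed, iteration, learner index).

    Attributes
    ----------
    state_ : final TriTrainState.
    models_ : dict name -> final fitted estimator.
    history_ : list of per-(iteration, learner) records.
    """

    def __init__(
        self,
        learner_factories: dict[str, Callable[[int], object]],
        stopping: StoppingRule | None = None,
        threshold: float | None = None,
        seed: int = 0,
    ):
        if len(learner_factories) != 3:
            raise ValueError("tri-training needs exactly three learners")
        self.learner_factories = dict(learner_factories)
        self.stopping = stopping or StoppingRule()
        self.threshold = threshold
        self.seed = seed

    # -- internals ---------------------------------------------------------
    def _fit_learner(self, name: str, idx: int, iteration: int, smiles, y):
        seed = (self.seed * 1_000_003 + iteration * 101 + idx) % (2**31)
        model = self.learner_factories[name](seed)
        model.fit(smiles, np.asarray(y))
        return model

    def _hard_labels(self, model, smiles: Sequence[str]) -> np.ndarray:
        probs = model.predict_proba(list(smiles))[:, 1]
        thr = self.threshold
        if thr is None:
            thr = getattr(model, "threshold_", 0.5)
        return (probs >= thr).astype(int)

    def _evaluate(self, models: dict, holdout_smiles, holdout_y) -> dict[str, float]:
        return {
            name: roc_auc(m.predict_proba(list(holdout_smiles))[:, 1], holdout_y)
            for name, m in models.items()
        }

    # -- main loop ---------------------------------------------------------
    def fit(
        self,
        labeled_smiles: Sequence[str],
        labeled_y: Sequence[int],
        pool_smiles: Sequence[str],
        holdout_smiles: Sequence[str],
        holdout_y: Sequence[int],
    ) -> "TriTraining":
        labeled_smiles = list(labeled_smiles)
        labeled_y = np.asarray(labeled_y, dtype=int)
        if len(np.unique(labeled_y)) < 2:
            raise ValueError("labeled set must contain both classes")
        overlap = set(holdout_smiles) & (set(labeled_smiles) | set(pool_smiles))
        if overlap:
            raise ValueError(f"hold-out leaks into training/pool: {sorted(overlap)[:3]}")
        names = list(self.learner_factories)
        state = TriTrainState(
            labeled_smiles=labeled_smiles,
            labeled_y=labeled_y,
            additions={n: [] for n in names},
            pool=list(pool_smiles),
            discarded=[],
            iteration=0,
            history=[],
        )
        models = {
            n: self._fit_learner(n, i, 0, labeled_smiles, labeled_y)
            for i, n in enumerate(names)
        }
        aucs = self._evaluate(models, holdout_smiles, holdout_y)
        for n in names:
            state.history.append(
                {
                    "iteration": 0,
                    "learner": n,
                    "train_size": state.training_size(n),
                    "n_labeled": len(labeled_smiles),
                    "n_pseudo": 0,
                    "holdout_auc": aucs[n],
                }
            )
        best_auc = max(aucs.values())
        while state.iteration < self.stopping.max_iterations:
            if not state.pool:
                break
            preds = {n: self._hard_labels(models[n], state.pool) for n in names}
            add_a, add_b, add_c, discarded = disagreement_route(
                preds[names[0]], preds[names[1]], preds[names[2]], state.pool
            )
            routed = {names[0]: add_a, names[1]: add_b, names[2]: add_c}
            n_routed = sum(len(v) for v in routed.values())
            assert n_routed + len(discarded) == len(state.pool)
            if n_routed == 0 and self.stopping.stop_on_agreement:
                break
            state.iteration += 1
            for n in names:
                state.additions[n].extend(
                    PseudoLabeled(s, lab, state.iteration, _teachers(n, names))
                    for s, lab in routed[n]
                )
            state.pool = discarded  # next iteration consumes the discards
            state.discarded = discarded
            models = {}
            for i, n in enumerate(names):
                extra = state.additions[n]
                smiles = labeled_smiles + [p.smiles for p in extra]
                y = np.concatenate([labeled_y, [p.label for p in extra]]).astype(int)
                models[n] = self._fit_learner(n, i, state.iteration, smiles, y)
            aucs = self._evaluate(models, holdout_smiles, holdout_y)
            for n in names:
                state.history.append(
                    {
                        "iteration": state.iteration,
                        "learner": n,
                        "train_size": state.training_size(n),
                        "n_labeled": len(labeled_smiles),
                        "n_pseudo": len(state.additions[n]),
                        "holdout_auc": aucs[n],
                    }
                )
            new_best = max(aucs.values())
            if new_best < best_auc + self.stopping.min_auc_gain:
                best_auc = max(best_auc, new_best)
                break
            best_auc = new_best
        self.state_ = state
        self.models_ = models
        self.history_ = state.history
        return self


def _teachers(dissenter: str, names: Sequence[str]) -> tuple[str, str]:
    others = tuple(n for n in names if n != dissenter)
    return (others[0], others[1])


def tri_train(
    labeled_smiles,
    labeled_y,
    pool_smiles,
    learner_factories,
    holdout_smiles,
    holdout_y,
    stopping: StoppingRule | None = None,
    seed: int = 0,
    threshold: float | None = None,
) -> TriTraining:
    """Functional wrapper over :class:`TriTraining`."""
    tt = TriTraining(learner_factories, stopping=stopping, threshold=threshold, seed=seed)
    return tt.fit(labeled_smiles, labeled_y, pool_smiles, holdout_smiles, holdout_y)


def history_report(tt: TriTraining | TriTrainState) -> pd.DataFrame:
    """Per-iteration/learner table: training size, labeled count, hold-out AUC."""
    history = tt.history if isinstance(tt, TriTrainState) else tt.state_.history
    if not history:
        raise ValueError("no completed evaluation")
    return pd.DataFrame(history)
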