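"""Self-training primitives and the dataset-level semisupervised loop.

The semisupervised scheme: the training set is partitioned into a small
labeled pool (LDS) and an unlabeled pool (UDS) with ratio m:(100-m).
The classifier is trained on the LDS and scores every UDS sample; for
each class that appears among the predictions, the most confident
sample(s) are moved into the LDS carrying their predicted class as a
pseudo-label.  The loop repeats — retraining between promotion rounds —
until the UDS is empty.

Confidence is the maximum softmax probability of the sample's row (the
standard self-training score); the scorer is pluggable so margin- or
entropy-based alternatives can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .data import LabeledImageSet, SSLPartition, make_ssl_partition


# --------------------------------------------------------------------
# confidence scoring
# --------------------------------------------------------------------
@dataclass(frozen=True)
class ConfidenceRecord:
    sample_id: object
    predicted_class: int
    confidence: float


def _max_softmax(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return probs.max(axis=1), probs.argmax(axis=1)


def _margin(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    part = np.sort(probs, axis=1)
    return part[:, -1] - part[:, -2], probs.argmax(axis=1)


def _neg_entropy(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ent = -np.sum(probs * np.log(probs + 1e-12), axis=1)
    return -ent, probs.argmax(axis=1)


_SCORERS: dict[str, Callable] = {
    "max_softmax": _max_softmax,
    "margin": _margin,
    "neg_entropy": _neg_entropy,
}


def confidence_scores(
    probs: np.ndarray,
    sample_ids: list | None = None,
    scorer: str | Callable = "max_softmax",
) -> list[ConfidenceRecord]:
    """One record per probability row.

    With the default scorer, confidence is the row maximum and the
    predicted class its position (argmax ties break toward the lowest
    class index, numpy convention).
    """
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2:
        raise ValueError("probs must be 2-d (samples x classes)")
    if (probs < -1e-5).any() or np.abs(probs.sum(axis=1) - 1.0).max() > 1e-5:
        raise ValueError("probability rows must be non-negative and sum to 1")
    fn = _SCORERS[scorer] if isinstance(scorer, str) else scorer
    conf, pred = fn(probs)
    if sample_ids is None:
        sample_ids = list(range(len(probs)))
    return [
        ConfidenceRecord(sid, int(c), float(s))
        for sid, c, s in zip(sample_ids, pred, conf)
    ]


def select_promotions(
    records: list[ConfidenceRecord], per_class: int = 1
) -> list[ConfidenceRecord]:
    """The ``per_class`` highest-confidence records of each predicted class.

    Classes with no predicted members contribute nothing that round.
    Within-class confidence ties break toward the smaller sample_id.
    """
    if not records:
        raise ValueError("records must be non-empty")
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    chosen: list[ConfidenceRecord] = []
    by_class: dict[int, list[ConfidenceRecord]] = {}
    for rec in records:
        by_class.setdefault(rec.predicted_class, []).append(rec)
    for cls in sorted(by_class):
        ranked = sorted(by_class[cls], key=lambda r: (-r.confidence, r.sample_id))
        chosen.extend(ranked[:per_class])
    return chosen


# --------------------------------------------------------------------
# dataset-level state and one loop step
# --------------------------------------------------------------------
@dataclass
class SSLState:
    """The evolving labeled/unlabeled partition with promotion provenance.

    ``lds.labels`` holds original labels for provenance "original" and
    model pseudo-labels for "pseudo".  ``uds.labels`` retains the hidden
    truth (or -1 when unknown) and is never used for training.
    """

    lds: LabeledImageSet
    uds: LabeledImageSet
    provenance: list[str] = field(default_factory=list)  # per lds sample
    promotion_iteration: list[int] = field(default_factory=list)  # -1 = original
    promotion_confidence: list[float] = field(default_factory=list)
    iteration: int = 0

    def __post_init__(self) -> None:
        if not self.provenance:
            n = len(self.lds)
            self.provenance = ["original"] * n
            self.promotion_iteration = [-1] * n
            self.promotion_confidence = [float("nan")] * n
        overlap = set(self.lds.sample_ids) & set(self.uds.sample_ids)
        if overlap:
            raise ValueError(f"LDS and UDS overlap: {sorted(overlap)[:3]}...")

    @property
    def total(self) -> int:
        return len(self.lds) + len(self.uds)

    @classmethod
    def from_partition(cls, partition: SSLPartition) -> "SSLState":
        return cls(lds=partition.lds, uds=partition.uds)


def ssl_step(state: SSLState, model, per_class: int = 1, scorer="max_softmax") -> SSLState:
    """One promotion round: score the UDS with a model trained on the
    current LDS and move the selected samples across with their
    pseudo-labels.  A remnant no larger than the class count is promoted
    wholesale.  Raises on an empty UDS (the caller owns the loop test)."""
    if len(state.uds) == 0:
        raise ValueError("UDS is empty; the loop should have terminated")
    probs = model.predict_proba(state.uds.to_tensors())
    records = confidence_scores(probs, sample_ids=list(range(len(state.uds))), scorer=scorer)
    noc = state.lds.n_classes
    if len(state.uds) <= noc:
        promoted = records
    else:
        promoted = select_promotions(records, per_class=per_class)
    pro_idx = [r.sample_id for r in promoted]
    keep_idx = [i for i in range(len(state.uds)) if i not in set(pro_idx)]
    moved = state.uds.subset(pro_idx)
    new_lds = LabeledImageSet(
        images=state.lds.images + moved.images,
        labels=np.concatenate([state.lds.labels, [r.predicted_class for r in promoted]]),
        class_names=state.lds.class_names,
        sample_ids=state.lds.sample_ids + moved.sample_ids,
    )
    it = state.iteration + 1
    return SSLState(
        lds=new_lds,
        uds=state.uds.subset(keep_idx),
        provenance=state.provenance + ["pseudo"] * len(promoted),
        promotion_iteration=state.promotion_iteration + [it] * len(promoted),
        promotion_confidence=state.promotion_confidence + [r.confidence for r in promoted],
        iteration=it,
    )


# --------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------
@dataclass
class SSLConfig:
    """Loop settings: promotions per class per round, warm-start epochs
    between rounds (cold_start retrains from scratch instead), and the
    confidence scorer."""

    per_class: int = 1
    epochs_per_iteration: int = 2
    cold_start: bool = False
    scorer: str = "max_softmax"
    seed: int = 0


def train_sscnn(
    train_set: LabeledImageSet,
    m_percent: float,
    train_config=None,
    ssl_config: SSLConfig | None = None,
    val_set: LabeledImageSet | None = None,
):
    """Partition a training set m:(100-m), run the self-training loop to
    exhaustion, and return (fitted classifier, per-iteration history
    DataFrame, promotion ledger DataFrame).

    With m=100 the UDS is empty and the result equals the supervised
    trainer on the same labeled set and seed.
    """
    from .estimators import SelfTrainingCNNClassifier
    from .training import TrainConfig, _estimator_from_config

    train_config = train_config or TrainConfig()
    ssl_config = ssl_config or SSLConfig()
    part = make_ssl_partition(train_set, m_percent, seed=ssl_config.seed)

    X = np.concatenate([part.lds.to_tensors(), part.uds.to_tensors()]) \
        if len(part.uds) else part.lds.to_tensors()
    y = np.concatenate([part.lds.labels, np.full(len(part.uds), -1, dtype=np.int64)])
    hidden = np.concatenate([part.lds.labels, part.uds.labels])

    clf = SelfTrainingCNNClassifier(
        estimator=_estimator_from_config(train_config),
        per_class=ssl_config.per_class,
        epochs_per_iteration=ssl_config.epochs_per_iteration,
        cold_start=ssl_config.cold_start,
        confidence=ssl_config.scorer,
    )
    val = (val_set.to_tensors(), val_set.labels) if val_set is not None else None
    clf.fit(X, y, hidden_labels=hidden, validation_data=val)

    ledger = clf.ledger_.copy()
    if len(ledger):
        all_ids = part.lds.sample_ids + part.uds.sample_ids
        ledger["sample_id"] = [all_ids[i] for i in ledger["sample_index"]]
    return clf, clf.history_, ledger


def write_history_csv(history: pd.DataFrame, path) -> None:
    history.to_csv(path, index=False)
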