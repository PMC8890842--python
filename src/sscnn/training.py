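"""Supervised training protocol and a minimal exhaustive grid search.

The default protocol is the published one: 60 epochs of Adam at learning
rate 0.001 with batch size 8, categorical cross-entropy on the softmax
output.  Training always runs the fixed epoch budget (no early
stopping); the final-epoch model is the one evaluated.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import pandas as pd
import yaml

from .architecture import ModelSpec
from .data import LabeledImageSet


@dataclass
class TrainConfig:
    epochs: int = 60
    optimizer: str = "adam"
    learning_rate: float = 0.001
    batch_size: int = 8
    loss: str = "categorical_crossentropy"
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning_rate must be > 0 and batch_size >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "categorical_crossentropy":
            raise ValueError(f"unsupported loss {self.loss!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TrainConfig":
        return cls(**yaml.safe_load(text))


def _estimator_from_config(config: TrainConfig, architecture: ModelSpec | None = None):
    from .estimators import CNNClassifier

    return CNNClassifier(
        architecture=architecture,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        beta1=config.beta1,
        beta2=config.beta2,
        random_state=config.seed,
    )


def train_supervised(
    spec: ModelSpec | None,
    train_set: LabeledImageSet,
    val_set: LabeledImageSet | None,
    config: TrainConfig | None = None,
):
    """Train the CNN on a labeled set; returns (classifier, history).

    The history DataFrame has one row per completed epoch with training
    loss/accuracy and, when a validation set is given, validation
    counterparts.
    """
    config = config or TrainConfig()
    if len(train_set) == 0:
        raise ValueError("empty training set")
    if val_set is not None and set(train_set.sample_ids) & set(val_set.sample_ids):
        raise ValueError("train and validation sets overlap")
    clf = _estimator_from_config(config, architecture=spec)
    val = (val_set.to_tensors(), val_set.labels) if val_set is not None else None
    clf.fit(train_set.to_tensors(), train_set.labels, validation_data=val)
    return clf, clf.history_


def grid_search(
    spec_grid: list[ModelSpec | None],
    config_grid: list[TrainConfig],
    train_set: LabeledImageSet,
    val_set: LabeledImageSet,
):
    """Exhaustively evaluate every (spec, config) pair by validation
    accuracy; ties break toward the earlier grid entry.

    Returns (best_spec, best_config, trials DataFrame).
    """
    if not spec_grid or not config_grid:
        raise ValueError("spec_grid and config_grid must be non-empty")
    Xv, yv = val_set.to_tensors(), val_set.labels
    rows = []
    best = None
    for si, spec in enumerate(spec_grid):
        for ci, config in enumerate(config_grid):
            clf, _ = train_supervised(spec, train_set, val_set, config)
            probs = clf.predict_proba(Xv)
            acc = float((probs.argmax(axis=1) == yv).mean())
            rows.append({"spec_index": si, "config_index": ci, "val_accuracy": acc})
            if best is None or acc > best[0]:
                best = (acc, spec, config)
    return best[1], best[2], pd.DataFrame(rows)
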