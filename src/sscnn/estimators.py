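"""scikit-learn-style estimators: the supervised CNN and its
self-training semisupervised wrapper.

``CNNClassifier`` trains the small landmark CNN with Adam on categorical
cross-entropy.  ``SelfTrainingCNNClassifier`` wraps a CNNClassifier in
the iterative self-training loop: train on the labeled pool, score the
unlabeled pool, promote the most confident prediction(s) of each
predicted class with their pseudo-labels, and repeat until the unlabeled
pool is empty.  Both follow the fit/predict/predict_proba contract and
compose with sklearn model-selection utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_is_fitted

from . import nn
from .architecture import ModelSpec, build_network, default_architecture
from .selftrain import confidence_scores, select_promotions


def _check_images(X: np.ndarray, side: int) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 4 or X.shape[1:] != (side, side, 3):
        raise ValueError(f"X must have shape (n, {side}, {side}, 3), got {X.shape}")
    return X


class CNNClassifier(ClassifierMixin, BaseEstimator):
    """Supervised CNN image classifier.

    Parameters mirror the published training protocol: 60 epochs, Adam
    with learning rate 0.001, batch size 8, categorical cross-entropy.

    Parameters
    ----------
    architecture : ModelSpec or None
        Layer specification; None means the default landmark CNN.
    epochs, learning_rate, batch_size : training protocol knobs.
    beta1, beta2 : Adam moment decay rates (framework defaults).
    shuffle : reshuffle the training set every epoch.
    warm_start : continue from the previously fitted weights and
        optimizer state instead of re-initializing.
    random_state : seeds weight init, shuffling and dropout; identical
        seeds and data give bit-identical models.

    Attributes
    ----------
    network_ : the fitted NumPy network.
    classes_ : class labels seen at fit.
    history_ : per-epoch DataFrame (loss/accuracy, and validation
        counterparts when validation data was supplied).
    """

    def __init__(
        self,
        architecture: ModelSpec | None = None,
        epochs: int = 60,
        learning_rate: float = 0.001,
        batch_size: int = 8,
        beta1: float = 0.9,
        beta2: float = 0.999,
        shuffle: bool = True,
        warm_start: bool = False,
        random_state: int | None = None,
    ):
        self.architecture = architecture
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.beta1 = beta1
        self.beta2 = beta2
        self.shuffle = shuffle
        self.warm_start = warm_start
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _spec(self) -> ModelSpec:
        return self.architecture if self.architecture is not None else default_architecture()

    def fit(self, X, y, validation_data: tuple[np.ndarray, np.ndarray] | None = None):
        """Train for ``epochs`` epochs; with epochs=0 the model is left at
        its (seeded) initialization and the history is empty."""
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs must be >= 0, batch_size >= 1, learning_rate > 0")
        spec = self._spec()
        side = spec.input_shape[0]
        noc = spec.n_classes
        X = _check_images(X, side)
        y = np.asarray(y, dtype=np.int64)
        if y.shape != (X.shape[0],):
            raise ValueError("y must be a 1-d label array aligned with X")
        if len(X) == 0:
            raise ValueError("empty training set")
        present = np.unique(y)
        if present.min() < 0 or present.max() >= noc:
            raise ValueError(f"labels must lie in [0, {noc})")

        resume = self.warm_start and hasattr(self, "network_")
        if not resume:
            if len(present) < noc:
                missing = sorted(set(range(noc)) - set(present.tolist()))
                raise ValueError(f"classes missing from training set: {missing}")
            seed = 0 if self.random_state is None else int(self.random_state)
            ss = np.random.SeedSequence(seed)
            s_init, s_shuffle = ss.spawn(2)
            self.network_ = build_network(spec, seed=s_init)
            self._rng = np.random.default_rng(s_shuffle)
            self.optimizer_ = nn.Adam(
                self.network_.trainable_params(),
                learning_rate=self.learning_rate,
                beta1=self.beta1,
                beta2=self.beta2,
            )
            self._history_rows: list[dict] = []
        self.classes_ = np.arange(noc)

        net, opt, rng = self.network_, self.optimizer_, self._rng
        eye = np.eye(noc, dtype=np.float64)
        n = len(X)
        for _ in range(self.epochs):
            order = rng.permutation(n) if self.shuffle else np.arange(n)
            losses, accs, weights = [], [], []
            for i in range(0, n, self.batch_size):
                idx = order[i : i + self.batch_size]
                loss, acc = net.train_batch(X[idx], eye[y[idx]], rng)
                opt.step(net.trainable_grads())
                losses.append(loss)
                accs.append(acc)
                weights.append(len(idx))
            row = {
                "epoch": len(self._history_rows) + 1,
                "loss": float(np.average(losses, weights=weights)),
                "accuracy": float(np.average(accs, weights=weights)),
            }
            if validation_data is not None:
                Xv, yv = validation_data
                vl, va = net.loss_and_accuracy(_check_images(Xv, side), np.asarray(yv))
                row["val_loss"], row["val_accuracy"] = vl, va
            self._history_rows.append(row)
        if self.epochs > 0:
            # running stats drift behind the moving weights; pin them to
            # the training-set population before any inference
            net.recalibrate_batchnorm(X)
        self.history_ = pd.DataFrame(self._history_rows)
        return self

    # ------------------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = _check_images(X, self._spec().input_shape[0])
        return self.network_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def get_weights(self) -> list[np.ndarray]:
        check_is_fitted(self, "network_")
        return self.network_.get_weights()

    def save(self, path) -> None:
        """Persist weights (npz) next to the architecture YAML."""
        check_is_fitted(self, "network_")
        np.savez(path, *self.network_.get_weights())

    def load_weights(self, path) -> "CNNClassifier":
        with np.load(path) as npz:
            weights = [npz[k] for k in npz.files]
        if not hasattr(self, "network_"):
            seed = 0 if self.random_state is None else int(self.random_state)
            self.network_ = build_network(self._spec(), seed=seed)
            self.classes_ = np.arange(self._spec().n_classes)
        self.network_.set_weights(weights)
        return self


class SelfTrainingCNNClassifier(ClassifierMixin, BaseEstimator):
    """Self-training semisupervised CNN (pseudo-labeling loop).

    fit(X, y) follows the sklearn semisupervised convention: entries of
    ``y`` equal to -1 are unlabeled.  The loop trains the base CNN on the
    labeled pool, predicts class probabilities for the unlabeled pool,
    computes each sample's confidence (maximum softmax probability), and
    promotes the ``per_class`` most confident samples of every predicted
    class into the labeled pool carrying their *predicted* class as
    pseudo-label.  Iterations repeat until the unlabeled pool is empty;
    if fewer than one-per-class samples remain, the remnant is promoted
    wholesale in the final step.  With no unlabeled samples the result is
    bit-identical to fitting the base CNN directly.

    Parameters
    ----------
    estimator : CNNClassifier or None
        Prototype base model (cloned); None means CNNClassifier defaults.
    per_class : promotions per predicted-present class per iteration.
    epochs_per_iteration : warm-start epochs after each promotion round.
    cold_start : retrain from scratch for the full epoch budget each
        iteration instead of warm-starting.
    confidence : "max_softmax" or a callable probs -> (confidence,
        predicted_class) arrays, to swap in margin/entropy scorers.
    random_state : overrides the base estimator's seed when set.

    Attributes
    ----------
    model_ : the final fitted CNNClassifier.
    history_ : per-iteration DataFrame (pool sizes, promotions, losses,
        labeled-pool accuracy, pseudo-label accuracy when the hidden
        truth was provided).
    ledger_ : one row per promoted sample (iteration, pseudo-label,
        confidence, hidden true label when provided).
    """

    def __init__(
        self,
        estimator: CNNClassifier | None = None,
        per_class: int = 1,
        epochs_per_iteration: int = 2,
        cold_start: bool = False,
        confidence: str = "max_softmax",
        random_state: int | None = None,
    ):
        self.estimator = estimator
        self.per_class = per_class
        self.epochs_per_iteration = epochs_per_iteration
        self.cold_start = cold_start
        self.confidence = confidence
        self.random_state = random_state

    def _make_base(self) -> CNNClassifier:
        base = clone(self.estimator) if self.estimator is not None else CNNClassifier()
        if self.random_state is not None:
            base.set_params(random_state=self.random_state)
        return base

    def fit(self, X, y, hidden_labels: np.ndarray | None = None,
            validation_data: tuple[np.ndarray, np.ndarray] | None = None):
        """Run the full self-training loop.

        ``hidden_labels`` optionally supplies the true labels of the
        unlabeled samples for diagnostics only — they never influence
        training.
        """
        if self.per_class < 1 or self.epochs_per_iteration < 0:
            raise ValueError("per_class must be >= 1 and epochs_per_iteration >= 0")
        y = np.asarray(y, dtype=np.int64)
        base = self._make_base()
        noc = base._spec().n_classes
        X = _check_images(np.asarray(X), base._spec().input_shape[0])
        labeled = np.flatnonzero(y >= 0)
        unlabeled = np.flatnonzero(y < 0)
        if len(labeled) == 0:
            raise ValueError("no labeled samples (all y are -1)")
        n_total = len(X)

        # evolving pools (indices into X); pseudo-labels fill in as we go
        lds = list(labeled)
        lds_y = list(y[labeled])
        uds = list(unlabeled)

        model = base.fit(X[lds], np.array(lds_y), validation_data=validation_data)
        history: list[dict] = []
        ledger: list[dict] = []
        iteration = 0
        while uds:
            probs = model.predict_proba(X[uds])
            records = confidence_scores(probs, sample_ids=list(uds), scorer=self.confidence)
            if len(uds) <= noc:
                promoted = records  # final remnant: promote everything
            else:
                promoted = select_promotions(records, per_class=self.per_class)
            iteration += 1
            for rec in promoted:
                lds.append(rec.sample_id)
                lds_y.append(rec.predicted_class)
                uds.remove(rec.sample_id)
                ledger.append({
                    "sample_index": rec.sample_id,
                    "iteration": iteration,
                    "pseudo_label": rec.predicted_class,
                    "confidence": rec.confidence,
                    "true_label": (int(hidden_labels[rec.sample_id])
                                   if hidden_labels is not None else -1),
                })
            if self.cold_start:
                model = self._make_base().fit(X[lds], np.array(lds_y),
                                              validation_data=validation_data)
            elif self.epochs_per_iteration > 0:
                model.set_params(warm_start=True, epochs=self.epochs_per_iteration)
                model.fit(X[lds], np.array(lds_y), validation_data=validation_data)
            row = {
                "iteration": iteration,
                "lds_size": len(lds),
                "uds_size": len(uds),
                "promotions": len(promoted),
            }
            loss, acc = model.network_.loss_and_accuracy(X[lds], np.array(lds_y))
            row["lds_loss"], row["lds_accuracy"] = loss, acc
            if hidden_labels is not None:
                pseudo = [r for r in ledger]
                correct = sum(r["pseudo_label"] == r["true_label"] for r in pseudo)
                row["pseudo_label_accuracy"] = correct / len(pseudo)
            history.append(row)
            assert len(lds) + len(uds) == n_total  # conservation
        self.model_ = model
        self.classes_ = model.classes_
        self.history_ = pd.DataFrame(history)
        self.ledger_ = pd.DataFrame(ledger)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict(X)
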