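"""Sequential network with a softmax classification head."""

from __future__ import annotations

import numpy as np

from .layers import Layer

F32 = np.float32
_EPS = 1e-7


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Network:
    """An ordered stack of layers ending in a linear class-score layer.

    The softmax is applied here rather than inside the last Dense layer so
    the cross-entropy gradient can use the fused (p - y) form.
    """

    def __init__(self, layers: list[Layer], n_classes: int):
        self.layers = layers
        self.n_classes = n_classes

    # ---- inference -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Row-stochastic class probabilities in input order."""
        out = np.empty((x.shape[0], self.n_classes), dtype=np.float64)
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i : i + batch_size].astype(F32, copy=False), training=False)
            out[i : i + batch_size] = softmax(logits.astype(np.float64))
        return out

    # ---- training --------------------------------------------------
    def train_batch(self, x: np.ndarray, y_onehot: np.ndarray, rng: np.random.Generator) -> tuple[float, float]:
        """One forward/backward pass; returns (mean cross-entropy, accuracy)
        for the batch.  Gradients are left in each layer's grad buffers
        for the optimizer."""
        logits = self.forward(x, training=True, rng=rng)
        p = softmax(logits.astype(np.float64))
        n = x.shape[0]
        loss = -np.mean(np.sum(y_onehot * np.log(p + _EPS), axis=1))
        acc = float(np.mean(p.argmax(axis=1) == y_onehot.argmax(axis=1)))
        dlogits = ((p - y_onehot) / n).astype(F32)
        for layer in reversed(self.layers):
            dlogits = layer.backward(dlogits)
        return float(loss), acc

    def loss_and_accuracy(self, x: np.ndarray, y: np.ndarray, batch_size: int = 256) -> tuple[float, float]:
        p = self.predict_proba(x, batch_size=batch_size)
        onehot = np.eye(self.n_classes)[y]
        loss = -np.mean(np.sum(onehot * np.log(p + _EPS), axis=1))
        acc = float(np.mean(p.argmax(axis=1) == y))
        return float(loss), acc

    def recalibrate_batchnorm(self, x: np.ndarray, max_samples: int = 512) -> None:
        """Reset every batchnorm layer's running statistics to the
        population statistics of the given (training) data.

        Running averages accumulated while the weights were still moving
        can sit far from the final activation distribution — on
        low-variance data badly enough to flip inference predictions —
        so after training we recompute them in one deterministic
        front-to-back pass (dropout off, earlier layers already
        recalibrated)."""
        from .layers import BatchNorm

        h = x[:max_samples].astype(F32, copy=False)
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                axes = tuple(range(h.ndim - 1))
                layer.running_mean[...] = h.mean(axis=axes)
                layer.running_var[...] = h.var(axis=axes)
            h = layer.forward(h, training=False)

    # ---- parameter plumbing ---------------------------------------
    def trainable_params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def trainable_grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def parameter_counts(self) -> list[int]:
        """Per-layer totals (incl. batchnorm running statistics)."""
        return [layer.n_params for layer in self.layers]

    def get_weights(self) -> list[np.ndarray]:
        """Copies of every array that defines the model state."""
        out = []
        for layer in self.layers:
            out.extend(p.copy() for p in layer.params())
            if hasattr(layer, "running_mean"):
                out.append(layer.running_mean.copy())
                out.append(layer.running_var.copy())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            for p in layer.params():
                p[...] = next(it)
            if hasattr(layer, "running_mean"):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)
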