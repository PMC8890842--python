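"""Layer implementations (forward + backward) on NHWC float32 arrays.

Conventions follow the common framework defaults this architecture family
is normally trained with: Glorot-uniform weight init, zero biases,
batchnorm with eps=1e-3 and running-stat momentum 0.9 (so inference
statistics are usable after short training runs), inverted dropout.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def glorot_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int, rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Layer:
    """Base class; stateless layers only need forward/backward."""

    trainable: bool = False

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    @property
    def n_params(self) -> int:
        """Total parameter count, including non-trainable statistics."""
        return sum(p.size for p in self.params())

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """kxk convolution, stride 1, zero "same" padding.

    Weights are stored (kh, kw, c_in, c_out); parameter count is
    c_out * (k*k*c_in + 1), matching the standard framework accounting.
    Implemented as k*k shifted matmuls so all heavy work is BLAS.
    """

    trainable = True

    def __init__(
        self,
        in_channels: int,
        filters: int,
        kernel_side: int,
        rng: np.random.Generator,
        needs_input_grad: bool = True,
    ):
        k = kernel_side
        fan_in = k * k * in_channels
        fan_out = k * k * filters
        self.w = glorot_uniform((k, k, in_channels, filters), fan_in, fan_out, rng)
        self.b = np.zeros(filters, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.k = k
        self.needs_input_grad = needs_input_grad

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, training, rng=None):
        n, h, w, c = x.shape
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cout = self.w.shape[3]
        # im2col (one large GEMM) pays off when c is small; otherwise the
        # k*k shifted matmuls avoid the 9x column-matrix materialization.
        dt = np.result_type(x.dtype, self.w.dtype)
        if c <= 8:
            cols = np.empty((n * h * w, k * k * c), dtype=dt)
            idx = 0
            for i in range(k):
                for j in range(k):
                    cols[:, idx * c : (idx + 1) * c] = xp[:, i : i + h, j : j + w, :].reshape(-1, c)
                    idx += 1
            y = (cols @ self.w.reshape(-1, cout)).reshape(n, h, w, cout)
            if training:
                self._cols, self._slices = cols, None
        else:
            y = np.zeros((n, h, w, cout), dtype=dt)
            yf = y.reshape(-1, cout)
            slices = []
            for i in range(k):
                for j in range(k):
                    sl = np.ascontiguousarray(xp[:, i : i + h, j : j + w, :]).reshape(-1, c)
                    yf += sl @ self.w[i, j]
                    slices.append(sl)
            if training:
                self._cols, self._slices = None, slices
        if training:
            self._shape = x.shape
        y += self.b
        return y

    def backward(self, dy):
        n, h, w, cout = dy.shape
        k = self.k
        p = k // 2
        c = self._shape[3]
        dyf = dy.reshape(-1, cout)
        if self._cols is not None:
            self.dw[...] = (self._cols.T @ dyf).reshape(k, k, c, cout)
        else:
            idx = 0
            for i in range(k):
                for j in range(k):
                    self.dw[i, j] = self._slices[idx].T @ dyf
                    idx += 1
        self.db[...] = dyf.sum(axis=0)
        self._cols = self._slices = None
        if not self.needs_input_grad:
            return None
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.result_type(dy.dtype, self.w.dtype))
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += (dyf @ self.w[i, j].T).reshape(n, h, w, c)
        return dxp[:, p : p + h, p : p + w, :]


class MaxPool2D(Layer):
    """2x2 max pooling with stride 2 (spatial dims must be even).

    Ties within a window route the gradient to the first maximal entry
    (row-major window order).
    """

    def __init__(self, pool_side: int = 2):
        self.s = pool_side

    def forward(self, x, training, rng=None):
        s = self.s
        m = x[:, 0::s, 0::s, :].copy()
        for i in range(s):
            for j in range(s):
                if i or j:
                    np.maximum(m, x[:, i::s, j::s, :], out=m)
        if training:
            self._x, self._m = x, m
        return m

    def backward(self, dy):
        s = self.s
        x, m = self._x, self._m
        dx = np.zeros(x.shape, dtype=dy.dtype)
        used = np.zeros(dy.shape, dtype=bool)
        for i in range(s):
            for j in range(s):
                take = (x[:, i::s, j::s, :] == m) & ~used
                np.copyto(dx[:, i::s, j::s, :], dy, where=take)
                used |= take
        self._x = self._m = None
        return dx


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channel/feature).

    Counts 4 parameters per channel: gamma/beta (trainable) plus the
    running mean/variance used at inference.
    """

    trainable = True

    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.9):
        self.gamma = np.ones(channels, dtype=F32)
        self.beta = np.zeros(channels, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.eps = eps
        self.momentum = momentum

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    @property
    def n_params(self) -> int:
        return self.gamma.size + self.beta.size + self.running_mean.size + self.running_var.size

    def forward(self, x, training, rng=None):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._xhat, self._inv, self._axes = xhat, inv, axes
            self._m = np.prod([x.shape[a] for a in axes])
        return self.gamma * xhat + self.beta

    def backward(self, dy):
        axes = self._axes
        xhat, inv, m = self._xhat, self._inv, self._m
        self.dgamma[...] = (dy * xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        dx = (inv / m) * (
            m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes)
        )
        return dx.astype(dy.dtype, copy=False)


class Dropout(Layer):
    """Inverted dropout: scales kept activations by 1/(1-rate)."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, training, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / F32(keep)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class ReLU(Layer):
    # operates in place: every preceding layer emits a fresh buffer
    def forward(self, x, training, rng=None):
        pos = x > 0
        if training:
            self._pos = pos
        x *= pos
        return x

    def backward(self, dy):
        dy *= self._pos
        self._pos = None
        return dy


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.3):
        self.slope = negative_slope

    def forward(self, x, training, rng=None):
        one = x.dtype.type(1.0)
        scale = np.where(x > 0, one, x.dtype.type(self.slope))
        if training:
            self._scale = scale
        x *= scale
        return x

    def backward(self, dy):
        dy *= self._scale
        self._scale = None
        return dy


class Flatten(Layer):
    def forward(self, x, training, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer; parameter count units * (in_features + 1)."""

    trainable = True

    def __init__(self, in_features: int, units: int, rng: np.random.Generator):
        self.w = glorot_uniform((in_features, units), in_features, units, rng)
        self.b = np.zeros(units, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, training, rng=None):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.w.T
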