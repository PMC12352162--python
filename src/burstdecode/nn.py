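"""A small, deterministic 1-D convolutional network in pure NumPy.

The architecture is fixed by the decoding design: three Conv1D blocks with
64, 128 and 64 filters (kernel size 3, 'same' padding, ReLU), each followed
by batch normalization, then global average pooling over time and a single
sigmoid output unit, trained with Adam on binary cross-entropy.

Everything is float32 and seeded, so training is bit-reproducible on a given
machine.  Activations are laid out internally as (channels, batch, time),
which lets each convolution run as one large matrix product over an im2col
buffer - the whole training loop stays inside BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ConvNet", "Adam", "sigmoid", "bce_with_logits", "train"]

F32 = np.float32


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z = np.asarray(logits, dtype=np.float64)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = (sigmoid(z) - y) / len(y)
    return float(loss), grad.astype(F32)


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class _Conv1dRelu:
    """'same'-padded 1-D convolution fused with a ReLU activation.

    Activations are (c, n, t); the kernel is stored flattened as
    (c_out, k * c_in) to match the im2col buffer.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng):
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.W = _glorot_uniform(rng, (c_out, kernel * c_in),
                                 fan_in=c_in * kernel, fan_out=c_out * kernel)
        self.b = np.zeros(c_out, dtype=F32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        c, n, t = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        cols = np.empty((self.k * c, n, t), dtype=F32)
        for j in range(self.k):
            cols[j * c:(j + 1) * c] = xp[:, :, j:j + t]
        return cols

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        c, n, t = x.shape
        cols = self._im2col(x)
        y = (self.W @ cols.reshape(self.k * c, n * t)).reshape(self.c_out, n, t)
        y += self.b[:, None, None]
        relu_mask = y > 0
        y *= relu_mask
        if training:
            self._cols, self._mask, self._in_shape = cols, relu_mask, x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, n, t = self._in_shape
        dy = dy * self._mask
        dy2 = dy.reshape(self.c_out, n * t)
        cols2 = self._cols.reshape(self.k * c, n * t)
        self.grads[0][...] = dy2 @ cols2.T
        self.grads[1][...] = dy2.sum(axis=1)
        dcols = (self.W.T @ dy2).reshape(self.k * c, n, t)
        pad = self.k // 2
        dxp = np.zeros((c, n, t + 2 * pad), dtype=F32)
        for j in range(self.k):
            dxp[:, :, j:j + t] += dcols[j * c:(j + 1) * c]
        return dxp[:, :, pad:pad + t]


class _BatchNorm1d:
    """Per-channel batch normalization over (batch, time)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(1, 2))
            var = x.var(axis=(1, 2))
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = (x - mean[:, None, None].astype(F32)) * inv[:, None, None]
        if training:
            self._xhat, self._inv = xhat, inv
        return self.gamma[:, None, None] * xhat + self.beta[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        m = dy.shape[1] * dy.shape[2]
        self.grads[0][...] = np.sum(dy * xhat, axis=(1, 2))
        self.grads[1][...] = np.sum(dy, axis=(1, 2))
        dxhat = dy * self.gamma[:, None, None]
        dx = (inv[:, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(1, 2), keepdims=True)
            - xhat * np.sum(dxhat * xhat, axis=(1, 2), keepdims=True)
        )
        return dx.astype(F32)


class _GlobalAveragePool:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._t = x.shape[2]
        return x.mean(axis=2)  # (c, n)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return (np.repeat(dy[:, :, None], self._t, axis=2) / F32(self._t))


class _Dense:
    """Single-logit output layer over the pooled features (c, n)."""

    def __init__(self, c_in: int, rng):
        self.W = _glorot_uniform(rng, (c_in,), fan_in=c_in, fan_out=1)
        self.b = np.zeros(1, dtype=F32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._x = x
        return self.W @ x + self.b  # (n,)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x @ dy
        self.grads[1][...] = dy.sum()
        return np.outer(self.W, dy).astype(F32)


class ConvNet:
    """Conv1D(+ReLU)/BatchNorm stack, global average pooling, sigmoid output."""

    def __init__(self, n_rows: int, conv_units: tuple[int, ...] = (64, 128, 64),
                 kernel_size: int = 3, bn_momentum: float = 0.9, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.layers = []
        c = n_rows
        for units in conv_units:
            self.layers.append(_Conv1dRelu(c, units, kernel_size, rng))
            self.layers.append(_BatchNorm1d(units, momentum=bn_momentum))
            c = units
        self.layers.append(_GlobalAveragePool())
        self.layers.append(_Dense(c, rng))

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """``x`` is (n, rows, t); returns logits of shape (n,)."""
        h = np.ascontiguousarray(np.transpose(x, (1, 0, 2)), dtype=F32)
        for layer in self.layers:
            h = layer.forward(h, training)
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits.astype(F32)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = np.empty(len(x), dtype=np.float64)
        for i in range(0, len(x), batch_size):
            out[i:i + batch_size] = sigmoid(self.forward(x[i:i + batch_size],
                                                         training=False))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        """All parameters and batch-norm running statistics, keyed by layer."""
        state = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                state[f"layer{i}_param{j}"] = p
            if isinstance(layer, _BatchNorm1d):
                state[f"layer{i}_running_mean"] = layer.running_mean
                state[f"layer{i}_running_var"] = layer.running_var
        return state

    def save(self, path) -> None:
        """Checkpoint the network to an .npz file."""
        np.savez(path, **self.state_dict())

    def load(self, path) -> "ConvNet":
        """Restore parameters saved by :meth:`save` into this architecture."""
        with np.load(path) as data:
            for key, target in self.state_dict().items():
                target[...] = data[key]
        return self


class Adam:
    """Adam with the framework-default step size (1e-3, betas 0.9/0.999)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= F32(lr_t) * m / (np.sqrt(v) + self.eps)


def train(net: ConvNet, x: np.ndarray, y: np.ndarray, *, epochs: int,
          batch_size: int, lr: float = 1e-3, seed: int = 0) -> list[float]:
    """Mini-batch Adam training; returns the per-epoch mean loss."""
    x = np.ascontiguousarray(x, dtype=F32)
    y = np.asarray(y, dtype=np.float64)
    opt = Adam(net.params, lr=lr)
    rng = np.random.default_rng(seed)
    history = []
    for _ in range(epochs):
        order = rng.permutation(len(x))
        losses = []
        for i in range(0, len(x), batch_size):
            idx = order[i:i + batch_size]
            logits = net.forward(x[idx], training=True)
            loss, dlogits = bce_with_logits(logits, y[idx])
            net.backward(dlogits)
            opt.step(net.grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history
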