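"""A small, deterministic neural-network engine on numpy.

Implements exactly the layer vocabulary the dual-branch classifiers need —
valid-padding 2-D convolution, non-overlapping max pooling, global average
pooling, dense layers, ReLU, inverted dropout — with explicit reverse-mode
gradients and Adam/Adamax optimisers.  Arrays are NHWC ``float64``.  All
randomness (initialisation, dropout masks, batch shuffling) flows through a
single ``numpy.random.Generator``, so training is bit-reproducible on one
thread.

This is an educational-scale engine: it favours clarity and determinism over
speed, which is the right trade-off for the image sizes this package trains.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "MaxPool2D",
    "GlobalAvgPool",
    "Flatten",
    "Dense",
    "ReLU",
    "Dropout",
    "Network",
    "Adam",
    "Adamax",
    "softmax",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Layer:
    """Base layer: ``weights``/``grads`` are parallel lists of arrays."""

    trainable = True

    def __init__(self) -> None:
        self.weights: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Valid-padding convolution, stride 1, He-initialised."""

    def __init__(self, in_channels: int, filters: int, ksize: int, rng: np.random.Generator):
        super().__init__()
        self.ksize = ksize
        self.in_channels = in_channels
        self.filters = filters
        fan_in = ksize * ksize * in_channels
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, filters))
        b = np.zeros(filters)
        self.weights = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[-1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {x.shape[-1]}")
        k = self.ksize
        # (N, Ho, Wo, C, k, k) -> (N, Ho, Wo, C*k*k)
        win = sliding_window_view(x, (k, k), axis=(1, 2))
        n, ho, wo = win.shape[:3]
        cols = win.reshape(n, ho, wo, -1)
        if train:
            self._cols = cols
            self._x_shape = x.shape
        return cols @ self.weights[0] + self.weights[1]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        w = self.weights[0]
        n, ho, wo, f = dout.shape
        cols2d = self._cols.reshape(-1, w.shape[0])
        dout2d = dout.reshape(-1, f)
        self.grads[0][...] = cols2d.T @ dout2d
        self.grads[1][...] = dout2d.sum(axis=0)
        dcols = (dout2d @ w.T).reshape(n, ho, wo, self.in_channels, self.ksize, self.ksize)
        dx = np.zeros(self._x_shape)
        for i in range(self.ksize):
            for j in range(self.ksize):
                dx[:, i : i + ho, j : j + wo, :] += dcols[:, :, :, :, i, j]
        return dx


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/cols that do not fill a
    window are cropped (floor semantics)."""

    trainable = False

    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        p = self.pool
        n, h, w, c = x.shape
        ho, wo = h // p, w // p
        xc = x[:, : ho * p, : wo * p, :]
        xr = xc.reshape(n, ho, p, wo, p, c)
        out = xr.max(axis=(2, 4))
        if train:
            self._mask = xr == out[:, :, None, :, None, :]
            self._x_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        p = self.pool
        n, ho, wo, c = dout.shape
        dxr = self._mask * dout[:, :, None, :, None, :]
        dx = np.zeros(self._x_shape)
        dx[:, : ho * p, : wo * p, :] = dxr.reshape(n, ho * p, wo * p, c)
        return dx


class GlobalAvgPool(Layer):
    trainable = False

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.ndim != 4:
            raise ValueError("GlobalAvgPool expects a 4-D feature map")
        if train:
            self._x_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x_shape
        return np.broadcast_to(dout[:, None, None, :], self._x_shape) / (h * w)


class Flatten(Layer):
    trainable = False

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x_shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._x_shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim))
        b = np.zeros(out_dim)
        self.weights = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weights[0] + self.weights[1]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.weights[0].T


class ReLU(Layer):
    trainable = False

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    trainable = False

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Adam:
    """Adam with configurable momentum parameters; ``lr`` is mutable so a
    learning-rate callback can adjust it between epochs."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}
        self._t = 0

    def step(self, weights: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (w, g) in enumerate(zip(weights, grads)):
            m = self._m.setdefault(i, np.zeros_like(w))
            v = self._v.setdefault(i, np.zeros_like(w))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            w -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Adamax(Adam):
    """Adamax: the infinity-norm variant of Adam."""

    def step(self, weights: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self._t += 1
        b1 = self.beta1
        for i, (w, g) in enumerate(zip(weights, grads)):
            m = self._m.setdefault(i, np.zeros_like(w))
            u = self._v.setdefault(i, np.zeros_like(w))
            m += (1 - b1) * (g - m)
            np.maximum(self.beta2 * u, np.abs(g), out=u)
            w -= self.lr * m / ((1 - b1**self._t) * (u + self.eps))


class Network:
    """A sequential stack trained with softmax cross-entropy.

    ``feature_index`` marks the layer whose *output* is the feature vector
    returned by :meth:`features` (by convention the ReLU after the last dense
    hidden layer); the final layer must produce class logits.
    """

    def __init__(self, layers: list[Layer], feature_index: int):
        self.layers = layers
        self.feature_index = feature_index

    # -- forward passes -------------------------------------------------
    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        chunks = [
            softmax(self.logits(x[i : i + batch_size], train=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(chunks) if chunks else np.zeros((0, 0))

    def features(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch_size):
            out = x[i : i + batch_size]
            for layer in self.layers[: self.feature_index + 1]:
                out = layer.forward(out, train=False)
            outs.append(out)
        return np.concatenate(outs)

    # -- training -------------------------------------------------------
    def train_batch(
        self,
        x: np.ndarray,
        y: np.ndarray,
        optimizer: Adam,
        trainable_mask: "list[bool] | None" = None,
        sample_weights: "np.ndarray | None" = None,
    ) -> float:
        """One gradient step on a minibatch; returns the batch loss.

        ``sample_weights`` reweights the per-sample cross-entropy terms
        (loss = Σ w·ce / Σ w); used to down- or up-weight pseudo-labelled
        samples relative to truly labelled ones.
        """
        logits = self.logits(x, train=True)
        probs = softmax(logits)
        n = len(x)
        eye = np.eye(probs.shape[1])
        ce = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None))
        if sample_weights is None:
            loss = ce.mean()
            grad = (probs - eye[y]) / n
        else:
            w = np.asarray(sample_weights, dtype=np.float64)
            wsum = w.sum()
            if wsum <= 0:
                return 0.0
            loss = float((w * ce).sum() / wsum)
            grad = (probs - eye[y]) * (w / wsum)[:, None]
        weights: list[np.ndarray] = []
        grads: list[np.ndarray] = []
        for idx in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[idx]
            grad = layer.backward(grad)
            frozen = trainable_mask is not None and not trainable_mask[idx]
            if layer.weights and not frozen:
                weights.extend(layer.weights)
                grads.extend(layer.grads)
        optimizer.step(weights, grads)
        return float(loss)

    # -- checkpointing --------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [w.copy() for layer in self.layers for w in layer.weights]

    def set_weights(self, flat: list[np.ndarray]) -> None:
        it = iter(flat)
        for layer in self.layers:
            for w in layer.weights:
                w[...] = next(it)
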