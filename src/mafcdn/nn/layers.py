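"""Trainable layers with explicit forward/backward passes.

Each layer caches what its backward pass needs during ``forward`` and frees
it when ``backward`` runs.  Parameters and their gradients live in plain
dicts keyed by name so the optimizer and checkpointing can walk them
generically.  Dropout draws from a generator injected at train time so a
whole network is deterministic given one seed.
"""

from __future__ import annotations

import numpy as np

from .ops import conv2d_forward, conv2d_input_grad, conv2d_weight_grad

DTYPE = np.float32


class Layer:
    """Base: subclasses fill ``params``/``grads`` and implement forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}  # non-trainable state (BN running stats)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


class Conv2d(Layer):
    """Stride-1 k x k convolution with 'same' zero padding and bias."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.pad = k // 2
        # He-uniform fan-in init, standard for ReLU networks
        bound = np.sqrt(6.0 / (in_ch * k * k))
        self.params["weight"] = rng.uniform(-bound, bound, (out_ch, in_ch, k, k)).astype(DTYPE)
        self.params["bias"] = np.zeros(out_ch, dtype=DTYPE)
        self._cols = None
        self._in_shape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y, cols = conv2d_forward(x, self.params["weight"], self.params["bias"], self.pad)
        if train:
            self._cols, self._in_shape = cols, x.shape
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads["weight"] = conv2d_weight_grad(g, self._cols, self.params["weight"].shape)
        self.grads["bias"] = g.sum(axis=(0, 2, 3))
        self._cols = None
        return conv2d_input_grad(g, self.params["weight"], self.pad)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with affine transform and running stats."""

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(ch, dtype=DTYPE)
        self.params["beta"] = np.zeros(ch, dtype=DTYPE)
        self.buffers["running_mean"] = np.zeros(ch, dtype=DTYPE)
        self.buffers["running_var"] = np.ones(ch, dtype=DTYPE)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.buffers["running_mean"] = ((1 - m) * self.buffers["running_mean"] + m * mean).astype(x.dtype)
            self.buffers["running_var"] = ((1 - m) * self.buffers["running_var"] + m * var).astype(x.dtype)
        else:
            mean = self.buffers["running_mean"].astype(x.dtype)
            var = self.buffers["running_var"].astype(x.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.params["gamma"][:, None, None] * xhat + self.params["beta"][:, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        n = g.shape[0] * g.shape[2] * g.shape[3]
        self.grads["gamma"] = (g * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = g.sum(axis=(0, 2, 3))
        gxh = g * self.params["gamma"][:, None, None]
        # standard batch-norm input gradient (batch statistics participate)
        t1 = gxh.sum(axis=(0, 2, 3), keepdims=True).transpose(1, 0, 2, 3)
        t2 = (gxh * xhat).sum(axis=(0, 2, 3), keepdims=True).transpose(1, 0, 2, 3)
        return inv[:, None, None] * (gxh - t1[:, 0] / n - xhat * t2[:, 0] / n)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = g * self._mask
        self._mask = None
        return g


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p: float) -> None:
        super().__init__()
        self.p = p
        self.rng: np.random.Generator | None = None  # injected by the network per run

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return g
        g = g * self._mask
        self._mask = None
        return g


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        idx = r.argmax(axis=-1)
        if train:
            self._idx, self._in_shape = idx, x.shape
        return np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(out, self._idx[..., None], g[..., None], axis=-1)
        self._idx = None
        return out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class UpsampleZero2x(Layer):
    """Resolution doubling by zero insertion; with the following 3x3 conv this
    forms the stride-2 transposed convolution of the transition-up layer."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        z = np.zeros((n, c, 2 * h, 2 * w), dtype=x.dtype)
        z[:, :, ::2, ::2] = x
        return z

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(g[:, :, ::2, ::2])


class RMSProp:
    """RMSprop with exponentially decayed learning rate."""

    def __init__(self, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-8, lr_decay: float = 0.995):
        self.lr0, self.rho, self.eps, self.lr_decay = lr, rho, eps, lr_decay
        self.cache: dict[int, dict[str, np.ndarray]] = {}
        self.epoch = 0

    @property
    def lr(self) -> float:
        return self.lr0 * self.lr_decay**self.epoch

    def step(self, layers: list[Layer]) -> None:
        for i, layer in enumerate(layers):
            if not layer.params:
                continue
            c = self.cache.setdefault(i, {k: np.zeros_like(v) for k, v in layer.params.items()})
            for k, p in layer.params.items():
                g = layer.grads[k]
                c[k] = self.rho * c[k] + (1.0 - self.rho) * g * g
                p -= (self.lr * g / (np.sqrt(c[k]) + self.eps)).astype(p.dtype)
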