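"""Minimal numpy implementation of the compact segment-quality CNN.

Architecture: three conv(3x3) -> batch-norm -> ReLU -> maxpool(2) blocks,
global average pooling and a 2-way softmax head. Trained with Adam,
weighted cross-entropy and L2 weight decay. Everything is plain numpy so
the model trains deterministically on one CPU; the layer set is exactly
what the quality-classification task needs, not a general framework.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

_EPS = 1e-5


def _im2col(x: np.ndarray, k: int = 3, pad: int = 1) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patch matrix for stride-1 'same' conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # view: (N, C, H, W, k, k)
    return view.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, h * w)


def _col2im(cols: np.ndarray, x_shape, k: int = 3, pad: int = 1) -> np.ndarray:
    """Adjoint of _im2col (accumulating scatter)."""
    n, c, h, w = x_shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    cols = cols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + h, j : j + w] += cols[:, :, i, j]
    return xp[:, :, pad : pad + h, pad : pad + w]


class Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = rng.standard_normal((c_out, c_in * 9)) * scale
        self.b = np.zeros(c_out)
        self.params = {"w": self.w, "b": self.b}
        self.decay = {"w"}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = _im2col(x)
        n, _, h, w = x.shape
        out = np.einsum("fk,nkp->nfp", self.w, self._cols) + self.b[None, :, None]
        return out.reshape(n, -1, h, w)

    def backward(self, grad: np.ndarray):
        n, f, h, w = grad.shape
        g = grad.reshape(n, f, h * w)
        self.grads = {
            "w": np.einsum("nfp,nkp->fk", g, self._cols),
            "b": g.sum(axis=(0, 2)),
        }
        dcols = np.einsum("fk,nfp->nkp", self.w, g)
        return _col2im(dcols, self._x_shape)


class BatchNorm:
    def __init__(self, c: int, momentum: float = 0.9):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.params = {"gamma": self.gamma, "beta": self.beta}
        self.decay: set[str] = set()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + _EPS)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, grad: np.ndarray):
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.grads = {
            "gamma": (grad * self._xhat).sum(axis=(0, 2, 3)),
            "beta": grad.sum(axis=(0, 2, 3)),
        }
        g = grad * self.gamma[None, :, None, None]
        dxhat_sum = g.sum(axis=(0, 2, 3), keepdims=True)
        gx_sum = (g * self._xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (
            g - dxhat_sum / m - self._xhat * gx_sum / m
        ) / self._std[None, :, None, None]


class ReLU:
    params: dict = {}
    decay: set = set()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray):
        return grad * self._mask


class MaxPool2:
    params: dict = {}
    decay: set = set()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = r.max(axis=(3, 5))
        mask = r == out[:, :, :, None, :, None]
        # distribute across ties to keep the adjoint exact
        self._mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        return out

    def backward(self, grad: np.ndarray):
        g = self._mask * grad[:, :, :, None, :, None]
        n, c, h, w = self._shape
        return g.reshape(n, c, h, w)


class GlobalAvgPool:
    params: dict = {}
    decay: set = set()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        self.b = np.zeros(d_out)
        self.params = {"w": self.w, "b": self.b}
        self.decay = {"w"}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray):
        self.grads = {"w": self._x.T @ grad, "b": grad.sum(axis=0)}
        return grad @ self.w.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, y: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean weighted CE loss and gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(y)
    w = class_weights[y]
    loss = float(-(w * np.log(p[np.arange(n), y] + 1e-12)).sum() / w.sum())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= w[:, None] / w.sum()
    return loss, grad


@dataclass
class Adam:
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    weight_decay: float = 0.0
    state: dict = dc_field(default_factory=dict)
    t: int = 0

    def step(self, layers) -> None:
        self.t += 1
        for li, layer in enumerate(layers):
            if not layer.params:
                continue
            for name, param in layer.params.items():
                g = layer.grads[name]
                if name in layer.decay and self.weight_decay:
                    g = g + self.weight_decay * param
                key = (li, name)
                if key not in self.state:
                    self.state[key] = (np.zeros_like(param), np.zeros_like(param))
                m, v = self.state[key]
                m = self.beta1 * m + (1 - self.beta1) * g
                v = self.beta2 * v + (1 - self.beta2) * g**2
                self.state[key] = (m, v)
                mhat = m / (1 - self.beta1**self.t)
                vhat = v / (1 - self.beta2**self.t)
                param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SmallCNN:
    """conv-norm-ReLU-pool x3, global average pool, 2-way softmax."""

    def __init__(self, input_size: int, channels=(8, 16, 32), seed: int = 0):
        if input_size % 8 != 0:
            raise ValueError("input_size must be divisible by 8 (three pools)")
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.channels = tuple(channels)
        self.layers: list = []
        c_in = 3
        for c_out in channels:
            self.layers += [
                Conv3x3(c_in, c_out, rng),
                BatchNorm(c_out),
                ReLU(),
                MaxPool2(),
            ]
            c_in = c_out
        self.layers.append(GlobalAvgPool())
        self.head = Dense(c_in, 2, rng)
        self.layers.append(self.head)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    # -- persistence ---------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        for li, layer in enumerate(self.layers):
            for name, p in getattr(layer, "params", {}).items():
                arrays[f"layer{li}_{name}"] = p
            if isinstance(layer, BatchNorm):
                arrays[f"layer{li}_running_mean"] = layer.running_mean
                arrays[f"layer{li}_running_var"] = layer.running_var
        return arrays

    def save(self, path: str | Path, meta: dict | None = None) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_arrays())
        config = {
            "input_size": self.input_size,
            "channels": list(self.channels),
            "meta": meta or {},
        }
        path.with_suffix(".json").write_text(json.dumps(config, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SmallCNN":
        path = Path(path)
        config = json.loads(path.with_suffix(".json").read_text())
        model = cls(input_size=config["input_size"], channels=config["channels"])
        arrays = np.load(path.with_suffix(".npz"))
        for li, layer in enumerate(model.layers):
            for name in getattr(layer, "params", {}):
                layer.params[name][...] = arrays[f"layer{li}_{name}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = arrays[f"layer{li}_running_mean"]
                layer.running_var[...] = arrays[f"layer{li}_running_var"]
        return model
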