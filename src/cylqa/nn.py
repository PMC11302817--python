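"""Minimal CPU neural-network layers with explicit backpropagation.

Just enough machinery for the ~35k-parameter classifier trained here: 3x3
same-padding convolutions, batch normalization, ReLU, 2x2 max pooling with
floor semantics, global average pooling, linear layers, inverted dropout, a
fused softmax/cross-entropy head and an Adam optimizer.  Spatial tensors are
carried channels-last (B, H, W, C) — convolution runs as nine shifted GEMMs,
which keeps every inner product on the contiguous channel axis.  Everything
is deterministic given the generators passed in.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state(self) -> dict[str, np.ndarray]:
        """All arrays needed to reconstruct the layer (params + buffers)."""
        return dict(self.params)

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32)


class Conv2d(Layer):
    """3x3 convolution with same padding, channels-last.

    Weights are stored as (3, 3, C_in, C_out); the forward pass accumulates
    ``x_pad[:, i:i+H, j:j+W, :] @ W[i, j]`` over the nine kernel offsets.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 input_grad: bool = True):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.input_grad = input_grad  # first layer can skip dx entirely
        std = np.sqrt(2.0 / (c_in * 9))
        self.params["W"] = rng.normal(0.0, std, (3, 3, c_in, c_out)).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[-1] != self.c_in:
            raise ValueError(
                f"Conv2d expected {self.c_in} input channels, got {x.shape[-1]}")
        b, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        wflat = np.ascontiguousarray(self.params["W"].reshape(9, c, self.c_out))
        out = np.empty((b * h * w, self.c_out), dtype=np.float32)
        out[:] = self.params["b"]
        slices = []
        for i in range(3):
            for j in range(3):
                xs = np.ascontiguousarray(
                    xp[:, i:i + h, j:j + w, :]).reshape(-1, c)
                out += xs @ wflat[3 * i + j]
                slices.append(xs)
        self._cache = (slices, x.shape, wflat)
        return out.reshape(b, h, w, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        slices, (b, h, w, c), wflat = self._cache
        d2 = np.ascontiguousarray(dout).reshape(-1, self.c_out)
        dw = np.empty_like(self.params["W"])
        dxp = (np.zeros((b, h + 2, w + 2, c), dtype=np.float32)
               if self.input_grad else None)
        for i in range(3):
            for j in range(3):
                xs = slices[3 * i + j]
                dw[i, j] = xs.T @ d2
                if dxp is not None:
                    dxp[:, i:i + h, j:j + w, :] += (
                        d2 @ wflat[3 * i + j].T).reshape(b, h, w, c)
        self.grads["W"] = dw
        self.grads["b"] = d2.sum(axis=0)
        return dxp[:, 1:-1, 1:-1, :] if dxp is not None else dout


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, x.shape)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        m = shape[0] * shape[1] * shape[2]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 1, 2))
        self.grads["beta"] = dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.params["gamma"]
        s1 = dxhat.sum(axis=(0, 1, 2))
        s2 = (dxhat * xhat).sum(axis=(0, 1, 2))
        return (inv / m) * (m * dxhat - s1 - xhat * s2)

    def state(self) -> dict[str, np.ndarray]:
        return {**self.params, "running_mean": self.running_mean,
                "running_var": self.running_var}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        super().load_state(state)
        self.running_mean = np.asarray(state["running_mean"], dtype=np.float32)
        self.running_var = np.asarray(state["running_var"], dtype=np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2x2(Layer):
    """2x2/stride-2 max pooling with floor semantics (odd trailing edge dropped)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        blocks = (x[:, :2 * ho, :2 * wo, :]
                  .reshape(b, ho, 2, wo, 2, c)
                  .transpose(0, 1, 3, 5, 2, 4)
                  .reshape(b, ho, wo, c, 4))
        self._arg = blocks.argmax(axis=-1)
        self._in_shape = x.shape
        return blocks.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._in_shape
        ho, wo = h // 2, w // 2
        dblocks = np.zeros((b, ho, wo, c, 4), dtype=dout.dtype)
        np.put_along_axis(dblocks, self._arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros((b, h, w, c), dtype=dout.dtype)
        dx[:, :2 * ho, :2 * wo, :] = (
            dblocks.reshape(b, ho, wo, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(b, 2 * ho, 2 * wo, c))
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._in_shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w),
                               self._in_shape).astype(dout.dtype)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (n_in + n_out))
        self.params["W"] = rng.uniform(-bound, bound, (n_out, n_in)).astype(np.float32)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = ((self.rng.random(x.shape) < keep) / keep).astype(np.float32)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    p = np.clip(probs, 1e-12, None)
    return float(-(onehot * np.log(p)).sum(axis=1).mean())


def softmax_ce_backward(probs: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    """Gradient of mean cross-entropy w.r.t. the logits."""
    return ((probs - onehot) / probs.shape[0]).astype(np.float32)


class Adam:
    def __init__(self, layers: list[Layer], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: list[dict[str, np.ndarray]] = [
            {k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers]
        self.v: list[dict[str, np.ndarray]] = [
            {k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers]

    def step(self) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for lay, m, v in zip(self.layers, self.m, self.v):
            for k, p in lay.params.items():
                g = lay.grads[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                p -= (self.lr * (m[k] / bc1)
                      / (np.sqrt(v[k] / bc2) + self.eps)).astype(np.float32)
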