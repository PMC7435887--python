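"""Minimal numpy neural-network core used by the two score generators.

Layers carry their parameters and gradients in plain dicts and implement an
explicit ``forward``/``backward`` pair; :class:`Sequential` chains them.  Only
what the two architectures need is provided: embedding lookup, stacked GRU
sequence layers (with full backpropagation through time), dilated causal 1-D
convolution (im2col + matmul), batch normalization, dense layers, ReLU, and
the RMSProp/Adam update rules.  All gradients are verified against central
finite differences in the test suite.
"""

from __future__ import annotations

import copy

import numpy as np

__all__ = [
    "Layer",
    "Dense",
    "ReLU",
    "Flatten",
    "Embedding",
    "GRU",
    "Conv1dDilated",
    "BatchNorm1d",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "RMSProp",
    "Adam",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits, axis=-1)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return float(loss), d / n


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {"W": _glorot(rng, d_in, d_out, (d_in, d_out)), "b": np.zeros(d_out)}
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.grads["W"] += x2.T @ d2
        self.grads["b"] += d2.sum(axis=0)
        return dout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Embedding(Layer):
    """Integer tokens -> trainable vectors; ``E`` is (vocab, dim), initialized
    randomly and optimized with the rest of the model."""

    def __init__(self, vocab: int, dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {"E": rng.normal(0.0, 0.1, size=(vocab, dim))}
        self.zero_grad()

    def forward(self, idx: np.ndarray, train: bool = True) -> np.ndarray:
        self._idx = np.asarray(idx, dtype=int)
        return self.params["E"][self._idx]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        np.add.at(self.grads["E"], self._idx, dout)
        return np.zeros(self._idx.shape)  # integer inputs carry no gradient


class GRU(Layer):
    """One GRU layer over a whole (batch, time, features) sequence.

    Gate order in the fused input projection is [update z | reset r | new n]:
    ``z = sigmoid(Wz x + Uz h)``, ``r = sigmoid(Wr x + Ur h)``,
    ``n = tanh(Wn x + r * (Un h))``, ``h' = (1 - z) n + z h``.
    Backward runs full BPTT over the stored per-step caches.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        H = hidden
        self.hidden = H
        self.params = {
            "W": _glorot(rng, d_in, H, (d_in, 3 * H)),
            "U_zr": _glorot(rng, H, H, (H, 2 * H)),
            "U_n": _glorot(rng, H, H, (H, H)),
            "b": np.zeros(3 * H),
        }
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, T, D = x.shape
        H = self.hidden
        W, U_zr, U_n, b = (self.params[k] for k in ("W", "U_zr", "U_n", "b"))
        Xp = x.reshape(B * T, D) @ W + b
        Xp = Xp.reshape(B, T, 3 * H)
        h = np.zeros((B, H))
        out = np.empty((B, T, H))
        cache = []
        for t in range(T):
            zr = h @ U_zr
            z = _sigmoid(Xp[:, t, :H] + zr[:, :H])
            r = _sigmoid(Xp[:, t, H : 2 * H] + zr[:, H:])
            hun = h @ U_n
            n = np.tanh(Xp[:, t, 2 * H :] + r * hun)
            h_new = (1.0 - z) * n + z * h
            cache.append((h, z, r, n, hun))
            h = h_new
            out[:, t] = h
        self._x, self._cache = x, cache
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, cache = self._x, self._cache
        B, T, D = x.shape
        H = self.hidden
        W, U_zr, U_n = (self.params[k] for k in ("W", "U_zr", "U_n"))
        dXp = np.empty((B, T, 3 * H))
        dU_zr = np.zeros_like(U_zr)
        dU_n = np.zeros_like(U_n)
        dh = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, z, r, n, hun = cache[t]
            dht = dout[:, t] + dh
            dz = dht * (h_prev - n)
            dn = dht * (1.0 - z)
            dh = dht * z
            dan = dn * (1.0 - n * n)
            dr = dan * hun
            dhun = dan * r
            dh += dhun @ U_n.T
            dU_n += h_prev.T @ dhun
            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            dzr = np.concatenate([daz, dar], axis=1)
            dh += dzr @ U_zr.T
            dU_zr += h_prev.T @ dzr
            dXp[:, t, :H] = daz
            dXp[:, t, H : 2 * H] = dar
            dXp[:, t, 2 * H :] = dan
        dXp2 = dXp.reshape(B * T, 3 * H)
        self.grads["W"] += x.reshape(B * T, D).T @ dXp2
        self.grads["b"] += dXp2.sum(axis=0)
        self.grads["U_zr"] += dU_zr
        self.grads["U_n"] += dU_n
        return (dXp2 @ W.T).reshape(B, T, D)


class Conv1dDilated(Layer):
    """Causal dilated 1-D convolution on (batch, channels, time) input.

    Left-pads by ``(kernel - 1) * dilation`` so output length equals input
    length; the receptive field of a stack is ``1 + (k - 1) * sum(dilations)``.
    """

    def __init__(
        self, c_in: int, c_out: int, kernel: int, dilation: int, rng: np.random.Generator
    ) -> None:
        super().__init__()
        self.c_in, self.c_out, self.kernel, self.dilation = c_in, c_out, kernel, dilation
        fan_in = c_in * kernel
        self.params = {
            "W": _glorot(rng, fan_in, c_out, (fan_in, c_out)),
            "b": np.zeros(c_out),
        }
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, T = x.shape
        k, d = self.kernel, self.dilation
        pad = (k - 1) * d
        xp = np.pad(x, ((0, 0), (0, 0), (pad, 0)))
        cols = np.stack([xp[:, :, j * d : j * d + T] for j in range(k)], axis=-1)
        cols2 = cols.transpose(0, 2, 1, 3).reshape(B, T, C * k)
        self._cols2, self._in_shape = cols2, x.shape
        out = cols2 @ self.params["W"] + self.params["b"]
        return out.transpose(0, 2, 1)  # (B, c_out, T)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, T = self._in_shape
        k, d = self.kernel, self.dilation
        pad = (k - 1) * d
        d2 = dout.transpose(0, 2, 1)  # (B, T, c_out)
        self.grads["W"] += self._cols2.reshape(-1, C * k).T @ d2.reshape(-1, self.c_out)
        self.grads["b"] += d2.reshape(-1, self.c_out).sum(axis=0)
        dcols2 = d2 @ self.params["W"].T  # (B, T, C*k)
        dcols = dcols2.reshape(B, T, C, k).transpose(0, 2, 1, 3)
        dxp = np.zeros((B, C, T + pad))
        for j in range(k):
            dxp[:, :, j * d : j * d + T] += dcols[:, :, :, j]
        return dxp[:, :, pad:]


class BatchNorm1d(Layer):
    """Per-channel normalization over (batch, time) for (B, C, T) input."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.zero_grad()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self._batch_mean, self._batch_var = mean, var
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * invstd[None, :, None]
        self._xhat, self._invstd, self._train = xhat, invstd, train
        return self.params["gamma"][None, :, None] * xhat + self.params["beta"][None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        self.grads["gamma"] += (dout * xhat).sum(axis=(0, 2))
        self.grads["beta"] += dout.sum(axis=(0, 2))
        dxhat = dout * self.params["gamma"][None, :, None]
        if not self._train:
            return dxhat * invstd[None, :, None]
        N = dout.shape[0] * dout.shape[2]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (invstd[None, :, None] / N) * (N * dxhat - s1 - xhat * s2)


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for layer, name in self.parameters())

    def get_state(self) -> list[dict[str, np.ndarray]]:
        return [copy.deepcopy(layer.params) for layer in self.layers]

    def set_state(self, state: list[dict[str, np.ndarray]]) -> None:
        for layer, params in zip(self.layers, state):
            layer.params = copy.deepcopy(params)


class _Optimizer:
    def __init__(self, model: Sequential, lr: float) -> None:
        self.model, self.lr = model, lr
        self.slots: dict[tuple[int, str], dict[str, np.ndarray]] = {}

    def _slot(self, layer: Layer, name: str, keys: tuple[str, ...]) -> dict[str, np.ndarray]:
        key = (id(layer), name)
        if key not in self.slots:
            self.slots[key] = {k: np.zeros_like(layer.params[name]) for k in keys}
        return self.slots[key]

    def step(self) -> None:  # pragma: no cover
        raise NotImplementedError


class RMSProp(_Optimizer):
    def __init__(self, model: Sequential, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-8):
        super().__init__(model, lr)
        self.rho, self.eps = rho, eps

    def step(self) -> None:
        for layer, name in self.model.parameters():
            g = layer.grads[name]
            s = self._slot(layer, name, ("v",))
            s["v"] = self.rho * s["v"] + (1 - self.rho) * g * g
            layer.params[name] -= self.lr * g / (np.sqrt(s["v"]) + self.eps)


class Adam(_Optimizer):
    def __init__(
        self,
        model: Sequential,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        super().__init__(model, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, name in self.model.parameters():
            g = layer.grads[name]
            s = self._slot(layer, name, ("m", "v"))
            s["m"] = b1 * s["m"] + (1 - b1) * g
            s["v"] = b2 * s["v"] + (1 - b2) * g * g
            mhat = s["m"] / (1 - b1**self.t)
            vhat = s["v"] / (1 - b2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
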