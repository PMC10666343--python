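"""A small NumPy neural-network library with explicit backpropagation.

Implements exactly the layers the peptide classifier needs — a mixed
discrete/continuous embedding front-end, 1-D valid convolution, max pooling,
batch normalisation, dropout, a bidirectional LSTM summarised by its final
hidden states, and dense layers — plus ``Sequential`` / ``Parallel``
containers and an Adam optimiser.  Everything is float64 and fully
deterministic given a seeded ``numpy.random.Generator``, which makes
training reproducible bit-for-bit and lets the test suite gradient-check
every layer against central finite differences.

Shapes: sequence layers operate on ``(B, T, D)`` arrays (batch, positions,
features); ``Flatten``, ``BiLSTM`` and ``Dense`` move to ``(B, F)``.
"""

from __future__ import annotations

from typing import Callable, Iterator, Sequence

import numpy as np


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def stable_sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """Logistic function ``(1 + e^{-x})^{-1}``, safe at extreme arguments."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


class Layer:
    """Base class: forward/backward plus named parameters and gradients."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}
        self.rng: np.random.Generator | None = None  # set by the trainer

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    # containers override these
    def iter_layers(self) -> Iterator["Layer"]:
        yield self

    def parameters(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        for layer in self.iter_layers():
            for k in sorted(layer.params):
                yield layer.params[k], layer.grads[k]

    def state_arrays(self) -> list[np.ndarray]:
        """All learned parameters plus persistent buffers, in a stable order."""
        out: list[np.ndarray] = []
        for layer in self.iter_layers():
            out.extend(layer.params[k] for k in sorted(layer.params))
            out.extend(layer.buffers[k] for k in sorted(layer.buffers))
        return out

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        expected = self.state_arrays()
        if len(arrays) != len(expected):
            raise ValueError(
                f"state mismatch: {len(arrays)} arrays for {len(expected)} slots"
            )
        for target, source in zip(expected, arrays):
            if target.shape != source.shape:
                raise ValueError(
                    f"state mismatch: shape {source.shape} for slot {target.shape}"
                )
            target[...] = source

    def num_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def set_rng(self, rng: np.random.Generator) -> None:
        for layer in self.iter_layers():
            layer.rng = rng


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def iter_layers(self):
        for layer in self.layers:
            yield from layer.iter_layers()


class Parallel(Layer):
    """Feed the same input through each branch; concatenate the outputs.

    Branch outputs must be 2-D ``(B, F_i)``; gradients w.r.t. the shared
    input are summed over branches.
    """

    def __init__(self, branches: Sequence[Layer]):
        super().__init__()
        self.branches = list(branches)
        self._widths: list[int] = []

    def forward(self, x, training=False):
        outs = [b.forward(x, training) for b in self.branches]
        self._widths = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        dx_total = None
        offset = 0
        for branch, width in zip(self.branches, self._widths):
            dx = branch.backward(dy[:, offset:offset + width])
            offset += width
            if dx is not None:
                dx_total = dx if dx_total is None else dx_total + dx
        return dx_total

    def iter_layers(self):
        for branch in self.branches:
            yield from branch.iter_layers()


class ChannelEmbedding(Layer):
    """Embed mixed discrete/continuous encoding channels, summed per position.

    The INM channel holds integers in {0..vocab-1} (0 = padding) and goes
    through a learned lookup table of width ``dim``.  Every other channel is
    a continuous scalar per position and goes through a learned linear map
    ``v -> v*w + b`` of width ``dim``.  The embedded streams are summed, so
    the output is ``(B, T, dim)`` regardless of how many channels are fed.
    """

    INM_VOCAB = 21  # pad symbol 0 plus residue codes 1..20

    def __init__(self, channels: Sequence[str], dim: int,
                 rng: np.random.Generator):
        super().__init__()
        self.channels = tuple(channels)
        self.dim = dim
        for i, name in enumerate(self.channels):
            if name == "INM":
                self.params[f"E{i}"] = rng.uniform(
                    -0.05, 0.05, size=(self.INM_VOCAB, dim))
            else:
                self.params[f"w{i}"] = glorot_uniform(rng, (dim,), 1, dim)
                self.params[f"b{i}"] = np.zeros(dim)
        self.zero_grad()

    def forward(self, x, training=False):
        B, T, C = x.shape
        if C != len(self.channels):
            raise ValueError(f"expected {len(self.channels)} channels, got {C}")
        self._cache = x
        y = np.zeros((B, T, self.dim))
        for i, name in enumerate(self.channels):
            if name == "INM":
                idx = x[:, :, i].astype(int)
                y += self.params[f"E{i}"][idx]
            else:
                y += x[:, :, i, None] * self.params[f"w{i}"] + self.params[f"b{i}"]
        return y

    def backward(self, dy):
        x = self._cache
        for i, name in enumerate(self.channels):
            if name == "INM":
                idx = x[:, :, i].astype(int).ravel()
                np.add.at(self.grads[f"E{i}"], idx, dy.reshape(-1, self.dim))
            else:
                self.grads[f"w{i}"] += np.einsum("bt,btd->d", x[:, :, i], dy)
                self.grads[f"b{i}"] += dy.sum(axis=(0, 1))
        return None  # the raw encoding matrix needs no gradient


class Conv1D(Layer):
    """1-D convolution over positions, valid (no) padding."""

    def __init__(self, in_dim: int, filters: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        self.params["W"] = glorot_uniform(
            rng, (kernel, in_dim, filters), kernel * in_dim, filters)
        self.params["b"] = np.zeros(filters)
        self.zero_grad()

    def forward(self, x, training=False):
        B, T, D = x.shape
        k = self.kernel
        if T < k:
            raise ValueError(f"sequence length {T} shorter than kernel {k}")
        self._cache = x
        T_out = T - k + 1
        y = np.broadcast_to(self.params["b"], (B, T_out, self.params["b"].size)).copy()
        W = self.params["W"]
        for i in range(k):
            y += x[:, i:i + T_out, :] @ W[i]
        return y

    def backward(self, dy):
        x = self._cache
        k = self.kernel
        T_out = dy.shape[1]
        W = self.params["W"]
        dx = np.zeros_like(x)
        for i in range(k):
            self.grads["W"][i] += np.einsum("btd,btf->df", x[:, i:i + T_out, :], dy)
            dx[:, i:i + T_out, :] += dy @ W[i].T
        self.grads["b"] += dy.sum(axis=(0, 1))
        return dx


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling over positions; a trailing remainder
    shorter than the window is dropped."""

    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def forward(self, x, training=False):
        B, T, D = x.shape
        T_out = T // self.pool
        windows = x[:, : T_out * self.pool, :].reshape(B, T_out, self.pool, D)
        self._argmax = windows.argmax(axis=2)
        self._in_shape = x.shape
        return np.take_along_axis(windows, self._argmax[:, :, None, :], axis=2)[
            :, :, 0, :]

    def backward(self, dy):
        B, T, D = self._in_shape
        T_out = T // self.pool
        dwin = np.zeros((B, T_out, self.pool, D))
        np.put_along_axis(dwin, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((B, T, D))
        dx[:, : T_out * self.pool, :] = dwin.reshape(B, T_out * self.pool, D)
        return dx


class BatchNorm(Layer):
    """Batch normalisation over (batch, position) per feature channel."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(dim)
        self.params["beta"] = np.zeros(dim)
        self.buffers["running_mean"] = np.zeros(dim)
        self.buffers["running_var"] = np.ones(dim)
        self.zero_grad()

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.buffers["running_mean"][...] = (
                m * self.buffers["running_mean"] + (1 - m) * mean)
            self.buffers["running_var"][...] = (
                m * self.buffers["running_var"] + (1 - m) * var)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        self._cache = (xhat, std, axes, x.shape)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        xhat, std, axes, shape = self._cache
        n = np.prod([shape[a] for a in axes])
        self.grads["gamma"] += (dy * xhat).sum(axis=axes)
        self.grads["beta"] += dy.sum(axis=axes)
        dxhat = dy * self.params["gamma"]
        # standard batch-norm gradient for the training-time statistics
        dx = (dxhat - dxhat.mean(axis=axes)
              - xhat * (dxhat * xhat).mean(axis=axes)) / std
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout needs an RNG in training mode")
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class _LSTMCell:
    """One LSTM direction; exposes forward over a sequence and full BPTT.

    Gate layout along the 4H axis: input, forget, candidate, output.
    The forget-gate bias is initialised to 1 (standard remedy for early
    forgetting).
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.Wx = glorot_uniform(rng, (in_dim, 4 * hidden), in_dim, 4 * hidden)
        self.Wh = glorot_uniform(rng, (hidden, 4 * hidden), hidden, 4 * hidden)
        self.b = np.zeros(4 * hidden)
        self.b[hidden:2 * hidden] = 1.0

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list]:
        B, T, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        caches = []
        for t in range(T):
            z = x[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i = stable_sigmoid(z[:, :H])
            f = stable_sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = stable_sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            caches.append((x[:, t, :], h, c, i, f, g, o, tanh_c))
            h = o * tanh_c
            c = c_new
        return h, caches

    def backward(self, dh_final: np.ndarray, caches: list,
                 dWx: np.ndarray, dWh: np.ndarray, db: np.ndarray
                 ) -> np.ndarray:
        H = self.hidden
        T = len(caches)
        B = dh_final.shape[0]
        dx = np.zeros((B, T, self.Wx.shape[0]))
        dh = dh_final
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = caches[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM summarised by the concatenated final hidden states.

    Output is ``(B, 2*hidden)``: the forward direction's state after the
    last position next to the backward direction's state after the first.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = _LSTMCell(in_dim, hidden, rng)
        self.bwd = _LSTMCell(in_dim, hidden, rng)
        for name, cell in (("f", self.fwd), ("b", self.bwd)):
            self.params[f"{name}_Wx"] = cell.Wx
            self.params[f"{name}_Wh"] = cell.Wh
            self.params[f"{name}_b"] = cell.b
        self.zero_grad()

    def forward(self, x, training=False):
        h_f, self._cache_f = self.fwd.forward(x)
        h_b, self._cache_b = self.bwd.forward(x[:, ::-1, :])
        return np.concatenate([h_f, h_b], axis=1)

    def backward(self, dy):
        H = self.fwd.hidden
        dx_f = self.fwd.backward(
            dy[:, :H], self._cache_f,
            self.grads["f_Wx"], self.grads["f_Wh"], self.grads["f_b"])
        dx_b = self.bwd.backward(
            dy[:, H:], self._cache_b,
            self.grads["b_Wx"], self.grads["b_Wh"], self.grads["b_b"])
        return dx_f + dx_b[:, ::-1, :]


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 activation: str = "linear"):
        super().__init__()
        if activation not in ("linear", "relu"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.params["W"] = glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim)
        self.params["b"] = np.zeros(out_dim)
        self.zero_grad()

    def forward(self, x, training=False):
        self._x = x
        y = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._mask = y > 0
            y = y * self._mask
        return y

    def backward(self, dy):
        if self.activation == "relu":
            dy = dy * self._mask
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T


def bce_with_logits(logits: np.ndarray, targets: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw logits; returns (loss, dlogits)."""
    z = logits
    y = targets
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (stable_sigmoid(z) - y) / z.size
    return loss, dz


class Adam:
    """Adam optimiser over a model's (parameter, gradient) pairs."""

    def __init__(self, model: Layer, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        pairs = list(model.parameters())
        self.m = [np.zeros_like(p) for p, _ in pairs]
        self.v = [np.zeros_like(p) for p, _ in pairs]

    def zero_grad(self) -> None:
        for layer in self.model.iter_layers():
            layer.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2 ** self.t) / (1 - b1 ** self.t)
        for slot, (p, g) in enumerate(self.model.parameters()):
            self.m[slot] = b1 * self.m[slot] + (1 - b1) * g
            self.v[slot] = b2 * self.v[slot] + (1 - b2) * g * g
            p -= lr_t * self.m[slot] / (np.sqrt(self.v[slot]) + self.eps)
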