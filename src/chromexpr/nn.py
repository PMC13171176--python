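"""Minimal 1D-CNN engine: layers, seeded init, Adam, and delta attribution.

Implements exactly what the promoter models need — valid 1D convolution,
ReLU, max-pooling, dense layers, inverted dropout and a sigmoid head — with
deterministic seeded initialization and a decoupled-weight-decay Adam
optimizer. Everything is NumPy; float32 for training.

Besides the usual forward/backward passes, every layer implements a
*delta-propagation* rule used for attribution: given a sample ``x`` and a
baseline ``b``, multipliers ``m`` are propagated from the output to the
input such that ``sum(m * (x - b)) == f(x) - f(b)`` holds exactly
(completeness / efficiency). Linear layers propagate their transpose;
elementwise nonlinearities use the rescale rule ``dy/dx -> (y_x - y_b) /
(x - b)`` with a gradient fallback at near-zero deltas; max-pooling
distributes each window's output delta over the window proportionally to
``dx_j / sum_j dx_j^2``, which preserves the window-level sum-to-delta
identity.
"""

from __future__ import annotations

import copy

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_EPS = 1e-9


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError

    def out_length(self, length):
        return length

    def delta_backward(self, m, x_in, b_in, x_out, b_out):
        """Propagate attribution multipliers from output to input."""
        raise NotImplementedError


class Conv1d(Layer):
    """Valid (no-padding) 1D convolution, channels-first (N, C, L)."""

    def __init__(self, in_channels, out_channels, kernel_size, rng):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size
        bound = 1.0 / np.sqrt(fan_in)
        self.params["W"] = rng.uniform(
            -bound, bound, size=(out_channels, in_channels, kernel_size)
        ).astype(np.float32)
        self.params["b"] = rng.uniform(-bound, bound, size=out_channels).astype(np.float32)

    def out_length(self, length):
        out = length - self.kernel_size + 1
        if out < 1:
            raise ValueError(
                f"input length {length} shorter than kernel width {self.kernel_size}"
            )
        return out

    def _cols(self, x):
        # (N, C, L) -> (N, L_out, C*k)
        v = sliding_window_view(x, self.kernel_size, axis=2)  # (N, C, L_out, k)
        return np.ascontiguousarray(v.transpose(0, 2, 1, 3)).reshape(
            x.shape[0], -1, self.in_channels * self.kernel_size
        )

    def forward(self, x, train=False):
        cols = self._cols(x)  # (N, L_out, C*k)
        N, L_out, ck = cols.shape
        Wmat = self.params["W"].reshape(self.out_channels, -1)
        # one large GEMM instead of N batched small ones
        y = cols.reshape(N * L_out, ck) @ Wmat.T + self.params["b"]
        self._cache = (x.shape, cols if train else None)
        return np.ascontiguousarray(
            y.reshape(N, L_out, self.out_channels).transpose(0, 2, 1)
        )

    def backward(self, dout, need_input_grad=True):
        x_shape, cols = self._cache
        N, C, L = x_shape
        d = np.ascontiguousarray(dout.transpose(0, 2, 1))  # (N, L_out, out)
        L_out = d.shape[1]
        dmat = d.reshape(-1, self.out_channels)
        self.grads["W"] = (dmat.T @ cols.reshape(-1, C * self.kernel_size)).reshape(
            self.params["W"].shape
        )
        self.grads["b"] = dmat.sum(axis=0)
        if not need_input_grad:
            return None
        return self._input_backward(d, x_shape)

    def _input_backward(self, d, x_shape):
        """Transpose map: (N, L_out, out) multipliers/grads -> (N, C, L)."""
        N, C, L = x_shape
        L_out = d.shape[1]
        Wmat = self.params["W"].reshape(self.out_channels, -1)
        dcols = (d.reshape(-1, self.out_channels) @ Wmat).reshape(
            N, L_out, C, self.kernel_size
        )
        dx = np.zeros(x_shape, dtype=d.dtype)
        for j in range(self.kernel_size):
            dx[:, :, j : j + L_out] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dx

    def delta_backward(self, m, x_in, b_in, x_out, b_out):
        # linear in x: multipliers are the transpose map, bias cancels in deltas
        d = np.ascontiguousarray(m.transpose(0, 2, 1))
        return self._input_backward(d, x_in.shape)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask

    def delta_backward(self, m, x_in, b_in, x_out, b_out):
        dx = x_in - b_in
        dy = x_out - b_out
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = dy / dx
        grad = (x_in > 0).astype(m.dtype)
        return m * np.where(np.abs(dx) > _EPS, slope, grad)


class Sigmoid(Layer):
    def forward(self, x, train=False):
        y = 1.0 / (1.0 + np.exp(-x))
        self._y = y
        return y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)

    def delta_backward(self, m, x_in, b_in, x_out, b_out):
        dx = x_in - b_in
        dy = x_out - b_out
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = dy / dx
        grad = x_out * (1.0 - x_out)
        return m * np.where(np.abs(dx) > _EPS, slope, grad)


class MaxPool1d(Layer):
    """Non-overlapping max pooling (stride == width); remainder dropped."""

    def __init__(self, width):
        super().__init__()
        self.width = width

    def out_length(self, length):
        out = length // self.width
        if out < 1:
            raise ValueError(f"pool width {self.width} collapses length {length} below 1")
        return out

    def _windows(self, x):
        N, C, L = x.shape
        L_out = L // self.width
        return x[:, :, : L_out * self.width].reshape(N, C, L_out, self.width)

    def forward(self, x, train=False):
        xr = self._windows(x)
        self._argmax = xr.argmax(axis=3)
        self._shape = x.shape
        return np.take_along_axis(xr, self._argmax[..., None], axis=3)[..., 0]

    def backward(self, dout):
        N, C, L = self._shape
        L_out = dout.shape[2]
        dxr = np.zeros((N, C, L_out, self.width), dtype=dout.dtype)
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None], axis=3)
        dx = np.zeros((N, C, L), dtype=dout.dtype)
        dx[:, :, : L_out * self.width] = dxr.reshape(N, C, -1)
        return dx

    def delta_backward(self, m, x_in, b_in, x_out, b_out):
        xr = self._windows(x_in)
        br = self._windows(b_in)
        dxw = xr - br  # (N, C, L_out, w)
        dy = (x_out - b_out)[..., None]  # (N, C, L_out, 1)
        denom = (dxw**2).sum(axis=3, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(denom > _EPS, dxw / denom, 0.0)
        mx = m[..., None] * dy * w
        N, C, L = x_in.shape
        out = np.zeros((N, C, L), dtype=m.dtype)
        L_out = x_out.shape[2]
        out[:, :, : L_out * self.width] = mx.reshape(N, C, -1)
        return out


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def delta_backward(self, m, x_in, b_in, x_out, b_out):
        return m.reshape(x_in.shape)


class Dense(Layer):
    def __init__(self, in_features, out_features, rng):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.params["W"] = rng.uniform(
            -bound, bound, size=(out_features, in_features)
        ).astype(np.float32)
        self.params["b"] = rng.uniform(-bound, bound, size=out_features).astype(np.float32)

    def forward(self, x, train=False):
        self._x = x if train else None
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]

    def delta_backward(self, m, x_in, b_in, x_out, b_out):
        return m @ self.params["W"]


class Dropout(Layer):
    """Inverted dropout; identity at inference. Draws from the network RNG."""

    def __init__(self, p, rng):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask.astype(dout.dtype)

    def delta_backward(self, m, x_in, b_in, x_out, b_out):
        return m


class Sequential:
    """A feed-forward stack with shared RNG (dropout) and param access."""

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for i in reversed(range(len(self.layers))):
            layer = self.layers[i]
            if i == 0 and isinstance(layer, Conv1d):
                layer.backward(dout, need_input_grad=False)
                return None
            dout = layer.backward(dout)
        return dout

    def predict(self, x, batch_size=4096):
        """Deterministic inference; returns a 1-D array of outputs."""
        outs = []
        for i in range(0, x.shape[0], batch_size):
            outs.append(self.forward(x[i : i + batch_size], train=False))
        return np.concatenate(outs, axis=0).reshape(x.shape[0], -1).squeeze(-1)

    def named_parameters(self):
        for li, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                yield f"{li}.{name}", layer, name, value

    def count_parameters(self):
        return int(sum(v.size for _, _, _, v in self.named_parameters()))

    def state_dict(self):
        return {k: v.copy() for k, _, _, v in self.named_parameters()}

    def load_state_dict(self, state):
        for key, layer, name, value in self.named_parameters():
            if key not in state:
                raise KeyError(f"missing parameter {key}")
            if state[key].shape != value.shape:
                raise ValueError(
                    f"shape mismatch for {key}: {state[key].shape} vs {value.shape}"
                )
            layer.params[name] = state[key].copy()

    def clone(self):
        return copy.deepcopy(self)

    def delta_attribution(self, x, baselines):
        """Per-channel, per-position attribution of ``f(x)`` against a set
        of baselines, averaged over baselines.

        ``x`` is a single sample (C, L); ``baselines`` is (B, C, L). The
        per-baseline scores satisfy completeness exactly:
        ``scores_b.sum() == f(x) - f(b)``; the returned mean therefore sums
        to ``f(x) - mean_b f(b)``.
        """
        x = np.asarray(x, dtype=np.float64)
        baselines = np.asarray(baselines, dtype=np.float64)
        if baselines.ndim == 2:
            baselines = baselines[None]
        if baselines.shape[1:] != x.shape:
            raise ValueError(
                f"baseline shape {baselines.shape[1:]} does not match sample {x.shape}"
            )
        B = baselines.shape[0]
        xs = np.broadcast_to(x, baselines.shape).copy()

        acts_x, acts_b = [xs], [baselines]
        cur_x, cur_b = xs, baselines
        for layer in self.layers:
            if isinstance(layer, Dropout):
                cur_x, cur_b = cur_x, cur_b  # identity at inference
            else:
                cur_x = layer.forward(cur_x, train=False)
                cur_b = layer.forward(cur_b, train=False)
            acts_x.append(cur_x)
            acts_b.append(cur_b)

        m = np.ones_like(cur_x)
        for i in reversed(range(len(self.layers))):
            layer = self.layers[i]
            m = layer.delta_backward(m, acts_x[i], acts_b[i], acts_x[i + 1], acts_b[i + 1])
        scores = m * (xs - baselines)  # (B, C, L)
        return scores.mean(axis=0)


class Adam:
    """Adam with L2-coupled weight decay (the decay term is added to the
    gradient *before* the moment updates, as torch's ``Adam(weight_decay=)``
    does). The coupling matters: for weights that receive no data gradient,
    the normalized decay step has magnitude ~lr regardless of the decay
    constant, which is what lets training actively silence uninformative
    input channels (e.g. under input scrambling)."""

    def __init__(self, net, lr, weight_decay=0.0, betas=(0.9, 0.999), eps=1e-8):
        self.net = net
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, _, _, v in net.named_parameters()}
        self.v = {k: np.zeros_like(v) for k, _, _, v in net.named_parameters()}

    def step(self):
        self.t += 1
        for key, layer, name, p in self.net.named_parameters():
            g = layer.grads[name] + self.weight_decay * p
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1**self.t)
            vhat = self.v[key] / (1 - self.b2**self.t)
            update = mhat / (np.sqrt(vhat) + self.eps)
            layer.params[name] = (p - self.lr * update).astype(p.dtype)
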