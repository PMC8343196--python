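"""A compact NumPy engine for one-dimensional convolutional networks.

Implements exactly the layer vocabulary the seed-spectra architectures need
— 1D convolution (stride 1, 'same' padding, odd kernels), batch
normalization, ELU, max/average pooling, dense layers, residual and
inception containers — with explicit forward/backward passes and an
SGD-with-momentum optimizer.  Everything is float32 and fully deterministic
under a seeded ``numpy.random.Generator``.

Data layout: convolutional activations are ``(N, C, L)`` (batch, channels,
spectral length); dense activations are ``(N, D)``.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Iterator

import numpy as np

__all__ = [
    "Layer", "Conv1d", "BatchNorm", "ELU", "MaxPool1d", "GlobalAvgPool1d",
    "Flatten", "Dense", "ResidualBlock", "InceptionBlock", "Network",
    "SGD", "softmax", "softmax_cross_entropy",
]

_F = np.float32


def _he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(_F)


class Layer:
    """Base layer: forward/backward plus parameter bookkeeping.

    ``frozen`` excludes a layer from optimization *and* (for BatchNorm)
    pins its normalization statistics — a frozen layer behaves exactly as
    at freeze time.
    """

    frozen: bool = False

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_items(self) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
        """Yield (name, parameter, gradient) triples."""
        return iter(())

    def state_items(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (name, array) for everything a checkpoint must carry."""
        for name, p, _ in self.param_items():
            yield name, p

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, p, _ in self.param_items():
            p[...] = state[prefix + name]

    def set_frozen(self, frozen: bool) -> None:
        self.frozen = frozen


def _conv_same(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """'same' 1D correlation of (N, Cin, L) with (Cout, Cin, k); returns
    (y, col) where col is the (N*L, Cin*k) im2col matrix for reuse."""
    n, cin, length = x.shape
    cout, _, k = w.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # N,Cin,L,k
    col = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(n * length, cin * k)
    y = col @ w.reshape(cout, cin * k).T
    return y.reshape(n, length, cout).transpose(0, 2, 1), col


class Conv1d(Layer):
    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.cin, self.cout, self.k = cin, cout, kernel
        self.w = _he_uniform(rng, (cout, cin, kernel), fan_in=cin * kernel)
        self.b = np.zeros(cout, dtype=_F)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._col: np.ndarray | None = None
        self._n_l: tuple[int, int] = (0, 0)

    def forward(self, x, train):
        x = x.astype(_F, copy=False)
        y, col = _conv_same(x, self.w)
        if train and not self.frozen:
            self._col, self._n_l = col, (x.shape[0], x.shape[2])
        return y + self.b[None, :, None]

    def backward(self, dy):
        n, length = dy.shape[0], dy.shape[2]
        dy_flat = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(n * length, self.cout)
        if self._col is not None:
            self.db[...] = dy.sum(axis=(0, 2))
            self.dw[...] = (dy_flat.T @ self._col).reshape(self.w.shape)
            self._col = None
        # dx is the 'same' correlation of dy with the flipped, transposed kernel
        w_t = np.ascontiguousarray(self.w[:, :, ::-1].transpose(1, 0, 2))
        dx, _ = _conv_same(dy.astype(_F, copy=False), w_t)
        return dx

    def param_items(self):
        yield "w", self.w, self.dw
        yield "b", self.b, self.db


class BatchNorm(Layer):
    """Channel-wise batch normalization for (N, C, L) or (N, D) input."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=_F)
        self.beta = np.zeros(channels, dtype=_F)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=_F)
        self.running_var = np.ones(channels, dtype=_F)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    @staticmethod
    def _axes(x):
        return (0, 2) if x.ndim == 3 else (0,)

    def _expand(self, v, ndim):
        return v[None, :, None] if ndim == 3 else v[None, :]

    def forward(self, x, train):
        x = x.astype(_F, copy=False)
        axes = self._axes(x)
        if train and not self.frozen:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var[...] = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._expand(mean, x.ndim)) * self._expand(invstd, x.ndim)
        mode = "train" if (train and not self.frozen) else "eval"
        self._cache = (mode, xhat, invstd)
        return self._expand(self.gamma, x.ndim) * xhat + self._expand(self.beta, x.ndim)

    def backward(self, dy):
        dy = dy.astype(_F, copy=False)
        axes = self._axes(dy)
        if self._cache[0] == "eval":
            # frozen statistics: normalization is a fixed affine map
            _, xhat, invstd = self._cache
            self.dgamma[...] = (dy * xhat).sum(axis=axes)
            self.dbeta[...] = dy.sum(axis=axes)
            return dy * self._expand(self.gamma * invstd, dy.ndim)
        _, xhat, invstd = self._cache
        m = dy.shape[0] if dy.ndim == 2 else dy.shape[0] * dy.shape[2]
        self.dgamma[...] = (dy * xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        g = self._expand(self.gamma * invstd, dy.ndim)
        sum_dy = self._expand(dy.sum(axis=axes), dy.ndim)
        sum_dy_xhat = self._expand((dy * xhat).sum(axis=axes), dy.ndim)
        return g / m * (m * dy - sum_dy - xhat * sum_dy_xhat)

    def param_items(self):
        yield "gamma", self.gamma, self.dgamma
        yield "beta", self.beta, self.dbeta

    def state_items(self):
        yield from super().state_items()
        yield "running_mean", self.running_mean
        yield "running_var", self.running_var

    def load_state(self, state, prefix=""):
        super().load_state(state, prefix)
        self.running_mean[...] = state[prefix + "running_mean"]
        self.running_var[...] = state[prefix + "running_var"]


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._cache = None

    def forward(self, x, train):
        x = x.astype(_F, copy=False)
        pos = x > 0
        y = np.where(pos, x, self.alpha * np.expm1(np.minimum(x, 0)))
        self._cache = (pos, y)
        return y.astype(_F, copy=False)

    def backward(self, dy):
        pos, y = self._cache
        return dy * np.where(pos, 1.0, y + self.alpha).astype(_F)


class MaxPool1d(Layer):
    """Max pooling along the spectral axis.

    ``kernel == stride`` (the between-block 2/2 pool) uses a fast reshape
    path; the stride-1 'same' pool of the inception branch uses sliding
    windows.
    """

    def __init__(self, kernel: int = 2, stride: int | None = None, same: bool = False):
        self.kernel = kernel
        self.stride = kernel if stride is None else stride
        self.same = same
        self._cache = None

    def forward(self, x, train):
        x = x.astype(_F, copy=False)
        n, c, length = x.shape
        if not self.same and self.kernel == self.stride:
            lo = length // self.kernel
            xt = x[:, :, : lo * self.kernel].reshape(n, c, lo, self.kernel)
            arg = xt.argmax(axis=3)
            self._cache = ("fast", arg, x.shape)
            return np.take_along_axis(xt, arg[..., None], axis=3)[..., 0]
        if not self.same:
            raise NotImplementedError("strided non-tiling pooling not needed")
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)), constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        arg = win.argmax(axis=3)
        self._cache = ("same", arg, x.shape, p)
        return np.take_along_axis(win, arg[..., None], axis=3)[..., 0].astype(_F)

    def backward(self, dy):
        if self._cache[0] == "fast":
            _, arg, shape = self._cache
            n, c, length = shape
            lo = dy.shape[2]
            dx = np.zeros((n, c, lo, self.kernel), dtype=_F)
            np.put_along_axis(dx, arg[..., None], dy[..., None].astype(_F), axis=3)
            out = np.zeros(shape, dtype=_F)
            out[:, :, : lo * self.kernel] = dx.reshape(n, c, lo * self.kernel)
            return out
        _, arg, shape, p = self._cache
        n, c, length = shape
        dxp = np.zeros((n, c, length + 2 * p), dtype=_F)
        # source position of window l's max is l + arg - 0 in padded coords
        pos = np.arange(length)[None, None, :] + arg
        np.add.at(dxp, (np.arange(n)[:, None, None], np.arange(c)[None, :, None], pos), dy)
        return dxp[:, :, p : p + length]


class GlobalAvgPool1d(Layer):
    """Average over the spectral axis, keeping a length-1 axis."""

    def forward(self, x, train):
        self._length = x.shape[2]
        return x.mean(axis=2, keepdims=True).astype(_F)

    def backward(self, dy):
        return np.repeat(dy / self._length, self._length, axis=2).astype(_F)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        self.w = _he_uniform(rng, (dout, din), fan_in=din)
        self.b = np.zeros(dout, dtype=_F)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, train):
        x = x.astype(_F, copy=False)
        if train and not self.frozen:
            self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy):
        dy = dy.astype(_F, copy=False)
        if self._x is not None:
            self.dw[...] = dy.T @ self._x
            self.db[...] = dy.sum(axis=0)
            self._x = None
        return dy @ self.w

    def param_items(self):
        yield "w", self.w, self.dw
        yield "b", self.b, self.db


class _Container(Layer):
    """Shared bookkeeping for layers that own named sublayers."""

    def named_sublayers(self) -> list[tuple[str, Layer]]:
        raise NotImplementedError

    def param_items(self):
        for name, sub in self.named_sublayers():
            for pname, p, g in sub.param_items():
                yield f"{name}.{pname}", p, g

    def state_items(self):
        for name, sub in self.named_sublayers():
            for sname, arr in sub.state_items():
                yield f"{name}.{sname}", arr

    def load_state(self, state, prefix=""):
        for name, sub in self.named_sublayers():
            sub.load_state(state, prefix=f"{prefix}{name}.")

    def set_frozen(self, frozen):
        self.frozen = frozen
        for _, sub in self.named_sublayers():
            sub.set_frozen(frozen)


class ResidualBlock(_Container):
    """conv-BN-ELU-conv-BN with an identity (or 1x1-projection) skip path,
    joined by addition and a trailing ELU."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator):
        self.conv1 = Conv1d(cin, cout, kernel, rng)
        self.bn1 = BatchNorm(cout)
        self.elu1 = ELU()
        self.conv2 = Conv1d(cout, cout, kernel, rng)
        self.bn2 = BatchNorm(cout)
        self.proj = Conv1d(cin, cout, 1, rng) if cin != cout else None
        self.elu_out = ELU()

    def named_sublayers(self):
        subs = [("conv1", self.conv1), ("bn1", self.bn1), ("elu1", self.elu1),
                ("conv2", self.conv2), ("bn2", self.bn2), ("elu_out", self.elu_out)]
        if self.proj is not None:
            subs.append(("proj", self.proj))
        return subs

    def forward(self, x, train):
        h = self.elu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        s = x if self.proj is None else self.proj.forward(x, train)
        return self.elu_out.forward(h + s, train)

    def backward(self, dy):
        d = self.elu_out.backward(dy)
        dh = self.bn2.backward(d)
        dh = self.conv2.backward(dh)
        dh = self.elu1.backward(dh)
        dh = self.bn1.backward(dh)
        dx = self.conv1.backward(dh)
        ds = d if self.proj is None else self.proj.backward(d)
        return dx + ds


class InceptionBlock(_Container):
    """Four parallel branches concatenated along the channel axis.

    Branch 1: 1x1 conv (f filters); branches 2/3: 1x1 bottleneck (f//2)
    then 1x3 / 1x5 conv (f filters each); branch 4: 3-wide stride-1 max
    pool then 1x1 conv (f filters).  Each conv is followed by BN + ELU.
    Output channels = 4 f.
    """

    def __init__(self, cin: int, f: int, rng: np.random.Generator):
        def cbe(ci, co, k):
            return [Conv1d(ci, co, k, rng), BatchNorm(co), ELU()]

        bott = max(1, f // 2)
        self.branches: list[list[Layer]] = [
            cbe(cin, f, 1),
            cbe(cin, bott, 1) + cbe(bott, f, 3),
            cbe(cin, bott, 1) + cbe(bott, f, 5),
            [MaxPool1d(kernel=3, stride=1, same=True)] + cbe(cin, f, 1),
        ]
        self.out_channels = 4 * f
        self._splits: list[int] = []

    def named_sublayers(self):
        return [
            (f"b{bi}.{li}", layer)
            for bi, branch in enumerate(self.branches)
            for li, layer in enumerate(branch)
        ]

    def forward(self, x, train):
        outs = []
        for branch in self.branches:
            h = x
            for layer in branch:
                h = layer.forward(h, train)
            outs.append(h)
        self._splits = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        dx = None
        offset = 0
        for branch, width in zip(self.branches, self._splits):
            d = dy[:, offset : offset + width, :]
            offset += width
            for layer in reversed(branch):
                d = layer.backward(d)
            dx = d if dx is None else dx + d
        return dx


class Network:
    """An ordered, named stack of layers ending in class logits.

    ``taps`` maps public feature names ('flatten', 'Fc1', 'Fc2') to the
    internal layer whose output realises them; 'Fc2' (or whatever maps to
    the sentinel '@softmax') is the softmax of the final logits.
    """

    def __init__(self, layers: list[tuple[str, Layer]], taps: dict[str, str]):
        self.layers = OrderedDict(layers)
        self.taps = dict(taps)

    # -- forward/backward ---------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x
        for layer in self.layers.values():
            h = layer.forward(h, train)
        return h

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        # a frozen prefix has no trainable parameters: stop backprop there
        items = list(self.layers.values())
        stop = 0
        while stop < len(items) and items[stop].frozen:
            stop += 1
        d = dlogits
        for layer in reversed(items[stop:]):
            d = layer.backward(d)
        return d

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = [softmax(self.forward(x[i : i + batch_size], train=False))
                for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(outs, axis=0)

    def features(self, x: np.ndarray, tap: str, batch_size: int = 256) -> np.ndarray:
        if tap not in self.taps:
            raise KeyError(
                f"unknown feature layer {tap!r}; valid names: {sorted(self.taps)}"
            )
        target = self.taps[tap]
        if target == "@softmax":
            return self.predict_proba(x, batch_size)
        if target not in self.layers:
            raise KeyError(f"tap {tap!r} points at missing layer {target!r}")
        outs = []
        for i in range(0, x.shape[0], batch_size):
            h = x[i : i + batch_size]
            for name, layer in self.layers.items():
                h = layer.forward(h, train=False)
                if name == target:
                    break
            outs.append(h.reshape(h.shape[0], -1))
        return np.concatenate(outs, axis=0)

    # -- parameters and state ----------------------------------------------

    def param_items(self):
        for name, layer in self.layers.items():
            for pname, p, g in layer.param_items():
                yield f"{name}.{pname}", p, g

    def trainable_params(self):
        for name, layer in self.layers.items():
            if layer.frozen:
                continue
            for pname, p, g in layer.param_items():
                yield f"{name}.{pname}", p, g

    def state_dict(self) -> OrderedDict[str, np.ndarray]:
        out = OrderedDict()
        for name, layer in self.layers.items():
            for sname, arr in layer.state_items():
                out[f"{name}.{sname}"] = arr.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self.layers.items():
            layer.load_state(state, prefix=f"{name}.")

    def freeze_before(self, boundary: str) -> list[str]:
        """Freeze every layer strictly before ``boundary``; returns names."""
        if boundary not in self.layers:
            raise KeyError(f"freeze boundary {boundary!r} not in {list(self.layers)}")
        frozen = []
        for name, layer in self.layers.items():
            if name == boundary:
                break
            layer.set_frozen(True)
            frozen.append(name)
        return frozen


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, learning_rate: float, momentum: float = 0.9):
        self.params = list(params)  # (name, param, grad)
        self.lr = learning_rate
        self.momentum = momentum
        self.velocity = {name: np.zeros_like(p) for name, p, _ in self.params}

    def step(self) -> None:
        for name, p, g in self.params:
            v = self.velocity[name]
            v *= self.momentum
            v -= self.lr * g
            p += v


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1))
    loss = float(np.mean(logsumexp - z[np.arange(n), labels]))
    p = softmax(logits)
    p[np.arange(n), labels] -= 1.0
    return loss, (p / n).astype(_F)
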