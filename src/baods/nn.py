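"""Minimal dense/convolutional network engine (numpy, CPU).

Implements exactly the layer set the ranking network needs — 2-D
convolution, batch normalization (2-D and 1-D), 2x2 max pooling,
flatten, fully connected layers and leaky-ReLU — each with a
hand-written backward pass, plus an Adam optimizer with L2 weight
decay. Forward passes cache inputs only when ``training=True`` so that
inference on the full-size input stays within a desktop memory budget.

All randomness is drawn from an injected ``numpy.random.Generator``;
weights and biases use the fan-in uniform scheme (biases are randomly
initialized, not zeroed).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: parameters live in ``params``/``grads`` dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def num_parameters(self) -> int:
        return sum(int(p.size) for p in self.params.values())


def _fan_in_uniform(
    rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype
) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Conv2d(Layer):
    def __init__(
        self,
        out_ch: int,
        in_ch: int,
        kh: int,
        kw: int,
        sh: int = 1,
        sw: int = 1,
        ph: int = 0,
        pw: int = 0,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = (sh, sw)
        self.padding = (ph, pw)
        fan_in = in_ch * kh * kw
        self.params["W"] = _fan_in_uniform(
            rng, (out_ch, in_ch, kh, kw), fan_in, dtype
        )
        self.params["b"] = _fan_in_uniform(rng, (out_ch,), fan_in, dtype)
        self.zero_grad()
        self._x: np.ndarray | None = None

    def _pad(self, x: np.ndarray) -> np.ndarray:
        ph, pw = self.padding
        if ph == 0 and pw == 0:
            return x
        return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))

    def _is_tiled(self, H: int) -> bool:
        # kernel exactly tiles the height axis (the two integration convs)
        kh, kw = self.params["W"].shape[2:]
        sh, sw = self.stride
        return (
            kh == sh and kw == 1 and sw == 1
            and self.padding == (0, 0) and H % kh == 0
        )

    def _windows(self, xp: np.ndarray) -> np.ndarray:
        kh, kw = self.params["W"].shape[2:]
        sh, sw = self.stride
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
        return win[:, :, ::sh, ::sw]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        xp = self._pad(x)
        self._x = xp if training else None
        W = self.params["W"]
        if self._is_tiled(xp.shape[2]):
            B, C, H, Wd = xp.shape
            kh = W.shape[2]
            x5 = xp.reshape(B, C, H // kh, kh, Wd)
            y = np.tensordot(x5, W[:, :, :, 0], axes=([1, 3], [1, 2]))
        else:
            win = self._windows(xp)  # (B, C, Ho, Wo, kh, kw) view
            y = np.tensordot(win, W, axes=([1, 4, 5], [1, 2, 3]))
        y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
        y += self.params["b"][None, :, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._x is not None, "backward requires a training forward"
        xp = self._x
        W = self.params["W"]
        kh, kw = W.shape[2:]
        sh, sw = self.stride
        ph, pw = self.padding
        if self._is_tiled(xp.shape[2]):
            B, C, H, Wd = xp.shape
            x5 = xp.reshape(B, C, H // kh, kh, Wd)
            dW = np.tensordot(dy, x5, axes=([0, 2, 3], [0, 2, 4]))
            self.grads["W"] += dW[:, :, :, None].astype(W.dtype)
            self.grads["b"] += dy.sum(axis=(0, 2, 3)).astype(W.dtype)
            dx5 = np.tensordot(dy, W[:, :, :, 0], axes=([1], [0]))
            dx = dx5.transpose(0, 3, 1, 4, 2).reshape(xp.shape)
            self._x = None
            return np.ascontiguousarray(dx)
        win = self._windows(xp)
        self.grads["W"] += np.tensordot(
            dy, win, axes=([0, 2, 3], [0, 2, 3])
        ).astype(W.dtype)
        self.grads["b"] += dy.sum(axis=(0, 2, 3)).astype(W.dtype)

        B, _, Ho, Wo = dy.shape
        dxp = np.zeros_like(xp)
        # (B, Ho, Wo, C, kh, kw) contribution of every output to its window
        contrib = np.tensordot(dy, W, axes=([1], [0]))
        for i in range(kh):
            for j in range(kw):
                dxp[
                    :, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw
                ] += contrib[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._x = None
        if ph or pw:
            H, Wd = dxp.shape[2] - 2 * ph, dxp.shape[3] - 2 * pw
            return dxp[:, :, ph : ph + H, pw : pw + Wd]
        return dxp


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2, floor division on odd extents."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, C, H, W = x.shape
        Ho, Wo = H // 2, W // 2
        xc = x[:, :, : 2 * Ho, : 2 * Wo]
        x6 = xc.reshape(B, C, Ho, 2, Wo, 2)
        y = x6.max(axis=(3, 5))
        if training:
            self._x6 = x6
            self._y = y
            self._in_shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x6, y = self._x6, self._y
        mask = x6 == y[:, :, :, None, :, None]
        # split gradient equally among tied maxima
        counts = mask.sum(axis=(3, 5), keepdims=True)
        g = mask * (dy[:, :, :, None, :, None] / counts)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        B, C, Ho, _, Wo, _ = x6.shape
        dx[:, :, : 2 * Ho, : 2 * Wo] = g.reshape(B, C, 2 * Ho, 2 * Wo)
        return dx


class _BatchNormBase(Layer):
    def __init__(
        self,
        num_features: int,
        axes: tuple[int, ...],
        shape_bc: tuple[int, ...],
        rng: np.random.Generator | None = None,
        dtype=np.float32,
        momentum: float = 0.1,
        eps: float = 1e-5,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.axes = axes
        self._bc = shape_bc  # broadcast shape for per-feature vectors
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(num_features, dtype=dtype)
        # biases randomly initialized on every layer
        self.params["beta"] = rng.uniform(
            -0.1, 0.1, size=num_features
        ).astype(dtype)
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self.zero_grad()

    def _r(self, v: np.ndarray) -> np.ndarray:
        return v.reshape(self._bc)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=self.axes)
            var = x.var(axis=self.axes)  # population variance
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mean.astype(self.running_mean.dtype)
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.astype(self.running_var.dtype)
            )
            std = np.sqrt(var + self.eps)
            xhat = (x - self._r(mean)) / self._r(std)
            self._xhat, self._std = xhat, std
        else:
            std = np.sqrt(self.running_var + self.eps)
            xhat = (x - self._r(self.running_mean)) / self._r(std)
        return self._r(self.params["gamma"]) * xhat + self._r(
            self.params["beta"]
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        n = dy.size // dy.shape[1] if dy.ndim == 4 else dy.shape[0]
        self.grads["gamma"] += (dy * xhat).sum(axis=self.axes).astype(
            self.params["gamma"].dtype
        )
        self.grads["beta"] += dy.sum(axis=self.axes).astype(
            self.params["beta"].dtype
        )
        g = self._r(self.params["gamma"] / std)
        mean_dy = self._r(dy.mean(axis=self.axes))
        mean_dy_xhat = self._r((dy * xhat).mean(axis=self.axes))
        dx = g * (dy - mean_dy - xhat * mean_dy_xhat)
        del self._xhat, self._std
        return dx


class BatchNorm2d(_BatchNormBase):
    def __init__(self, num_features: int, **kw) -> None:
        super().__init__(
            num_features, axes=(0, 2, 3), shape_bc=(1, num_features, 1, 1), **kw
        )


class BatchNorm1d(_BatchNormBase):
    def __init__(self, num_features: int, **kw) -> None:
        super().__init__(
            num_features, axes=(0,), shape_bc=(1, num_features), **kw
        )


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.01) -> None:
        super().__init__()
        self.slope = negative_slope

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._pos = x > 0
        return np.where(x > 0, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._pos, dy, self.slope * dy)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(
        self,
        out_features: int,
        in_features: int,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["W"] = _fan_in_uniform(
            rng, (out_features, in_features), in_features, dtype
        )
        self.params["b"] = _fan_in_uniform(
            rng, (out_features,), in_features, dtype
        )
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += (dy.T @ self._x).astype(self.params["W"].dtype)
        self.grads["b"] += dy.sum(axis=0).astype(self.params["b"].dtype)
        dx = dy @ self.params["W"]
        del self._x
        return dx


class Network:
    """A plain sequential stack of layers."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def num_parameters(self) -> int:
        return sum(layer.num_parameters() for layer in self.layers)

    def parameters(self):
        """Yield (layer_index, name, param, grad) for every parameter."""
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                yield i, name, p, layer.grads[name]

    def state_arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                out[f"{i}.{name}"] = p
            if isinstance(layer, _BatchNormBase):
                out[f"{i}.running_mean"] = layer.running_mean
                out[f"{i}.running_var"] = layer.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = state[f"{i}.{name}"].copy()
            if isinstance(layer, _BatchNormBase):
                layer.running_mean = state[f"{i}.running_mean"].copy()
                layer.running_var = state[f"{i}.running_var"].copy()
            layer.zero_grad()


class Adam:
    """Adaptive moment estimation with (coupled) L2 weight decay."""

    def __init__(
        self,
        network: Network,
        lr: float = 0.001,
        betas: tuple[float, float] = (0.9, 0.999),
        weight_decay: float = 0.0002,
        eps: float = 1e-8,
    ) -> None:
        self.net = network
        self.lr = lr
        self.b1, self.b2 = betas
        self.wd = weight_decay
        self.eps = eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        for i, name, p, g in self.net.parameters():
            key = (i, name)
            grad = g + self.wd * p
            m = self.m.setdefault(key, np.zeros_like(p))
            v = self.v.setdefault(key, np.zeros_like(p))
            m *= self.b1
            m += (1 - self.b1) * grad
            v *= self.b2
            v += (1 - self.b2) * grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
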