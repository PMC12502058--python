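"""Minimal numpy neural-net layers with explicit forward/backward passes.

Implements exactly what the tiny convolutional backbone needs — stride-1
3x3 convolution (im2col), ReLU, 2x2 max pooling, flatten, and dense layers —
plus an Adam optimizer.  Every layer caches what its backward pass needs,
returns the gradient w.r.t. its input (so attribution methods can read
input-space gradients), and exposes its parameters for checkpointing.
All computation is float64 and fully deterministic given the init RNG.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: dict  # name -> array
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (configurable) stride-1 convolution with 'same' zero padding."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, ksize
        self.pad = ksize // 2
        fan_in = in_ch * ksize * ksize
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, ksize, ksize)),
            "b": np.zeros(out_ch),
        }

    def forward(self, x):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        # (n, c, h, w, k, k) windows -> columns (n*h*w, c*k*k)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, -1)
        self._cache = (cols, x.shape)
        out = cols @ self.params["W"].reshape(self.out_ch, -1).T + self.params["b"]
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, (n, c, h, w) = self._cache
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        self.grads["W"] = (dflat.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"] = dflat.sum(axis=0)
        dcols = (dflat @ self.params["W"].reshape(self.out_ch, -1)).reshape(
            n, h, w, c, self.k, self.k
        )
        dxp = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if self.pad:
            return dxp[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dxp


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even.

    Gradient at a tie is split equally among the tied positions.
    """

    def __init__(self, size: int = 2):
        super().__init__()
        self.s = size

    def forward(self, x):
        n, c, h, w = x.shape
        s = self.s
        xr = x.reshape(n, c, h // s, s, w // s, s)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        self._cache = (mask / mask.sum(axis=(3, 5), keepdims=True), x.shape)
        return out

    def backward(self, dout):
        mask, shape = self._cache
        return (mask * dout[:, :, :, None, :, None]).reshape(shape)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        out = []
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                out.append((f"{i}.{name}", layer))
        return out


class Adam:
    def __init__(self, modules: list[Sequential], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.entries = []  # (layer, param name)
        for mod in modules:
            for layer in mod.layers:
                for name in layer.params:
                    self.entries.append((layer, name))
        self.m = [np.zeros_like(layer.params[n]) for layer, n in self.entries]
        self.v = [np.zeros_like(layer.params[n]) for layer, n in self.entries]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (layer, name) in enumerate(self.entries):
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for layer, name in self.entries:
            layer.grads.pop(name, None)


def state_dict(modules: dict[str, Sequential]) -> dict[str, np.ndarray]:
    out = {}
    for mod_name, mod in modules.items():
        for i, layer in enumerate(mod.layers):
            for pname, arr in layer.params.items():
                out[f"{mod_name}.{i}.{pname}"] = arr
    return out


def load_state_dict(modules: dict[str, Sequential], state: dict[str, np.ndarray]) -> None:
    for key, arr in state.items():
        mod_name, idx, pname = key.rsplit(".", 2)
        layer = modules[mod_name].layers[int(idx)]
        if layer.params[pname].shape != arr.shape:
            raise ValueError(f"shape mismatch for {key}")
        layer.params[pname] = np.array(arr, dtype=np.float64)
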