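"""Neural-network layers on top of the autograd core.

Convolution is implemented as im2col (via ``sliding_window_view``) followed by
a single BLAS matmul, with a hand-written backward; batch norm likewise has a
fused backward using the standard normalization gradient.  These three fused
ops dominate the runtime of a training step.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, is_grad_enabled

__all__ = [
    "Module", "Parameter", "Sequential", "Linear", "Conv2d", "BatchNorm2d",
    "ReLU", "MaxPool2d", "global_avg_pool", "global_max_pool",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)
        self.requires_grad = True  # immune to no_grad at construction time


class Module:
    """Minimal module container: tracks parameters, train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- flat state dict for single-file checkpoints --------------------------
    def state_arrays(self, prefix: str = "") -> dict:
        out = {}
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                out[key] = v.data
            elif isinstance(v, np.ndarray):
                out[key] = v
            elif isinstance(v, Module):
                out.update(v.state_arrays(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(prefix=f"{key}.{i}."))
        return out

    def load_state_arrays(self, arrays: dict, prefix: str = "") -> None:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                v.data = arrays[key].astype(v.data.dtype).reshape(v.data.shape)
            elif isinstance(v, np.ndarray):
                self.__dict__[name] = arrays[key].astype(v.dtype).reshape(v.shape)
            elif isinstance(v, Module):
                v.load_state_arrays(arrays, prefix=key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_arrays(arrays, prefix=f"{key}.{i}.")


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


def _kaiming(rng, fan_in, shape):
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng=None, bias: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming(rng, in_features, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    """2-D convolution, NCHW layout, symmetric zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng=None, bias: bool = False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_kaiming(rng, fan_in, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None
        self.stride = stride
        self.padding = padding
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        w = self.weight
        s, p, k = self.stride, self.padding, self.kernel
        xd = x.data
        B, C, H, W = xd.shape
        if p:
            xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = xd
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        if Ho < 1 or Wo < 1:
            raise ValueError(f"input {H}x{W} too small for kernel {k} stride {s}")
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]                     # B,C,Ho,Wo,k,k (view)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * k * k)
        cols = np.ascontiguousarray(cols)
        wmat = w.data.reshape(w.data.shape[0], -1)    # O, C*k*k
        out_data = (cols @ wmat.T).reshape(B, Ho, Wo, -1).transpose(0, 3, 1, 2)
        out_data = np.ascontiguousarray(out_data)

        parents = [x, w]

        def backward(g):
            gmat = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, -1)  # BHW, O
            if w.requires_grad:
                gw = gmat.T @ cols
                w._accum(gw.reshape(w.data.shape))
            if x.requires_grad:
                gcols = gmat @ wmat                  # BHW, C*k*k
                gcols = gcols.reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
                gxp = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        gxp[:, :, i:i + Ho * s:s, j:j + Wo * s:s] += gcols[..., i, j]
                x._accum(gxp[:, :, p:p + H, p:p + W] if p else gxp)

        out = Tensor._from_op(out_data, tuple(parents), backward)
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1, 1, 1)
        return out


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel, self.stride, self.padding
        xd = x.data
        B, C, H, W = xd.shape
        if p:
            xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)),
                        constant_values=-np.inf)
        else:
            xp = xd
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]
        out_data = win.max(axis=(4, 5))

        def backward(g):
            if not x.requires_grad:
                return
            gxp = np.zeros_like(xp)
            claimed = np.zeros(out_data.shape, dtype=bool)
            for i in range(k):
                for j in range(k):
                    elem = win[..., i, j]
                    hit = (elem == out_data) & ~claimed
                    claimed |= hit
                    gxp[:, :, i:i + Ho * s:s, j:j + Wo * s:s] += g * hit
            x._accum(gxp[:, :, p:p + H, p:p + W] if p else gxp)

        return Tensor._from_op(np.ascontiguousarray(out_data), (x,), backward)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features, dtype=np.float32))
        self.beta = Parameter(np.zeros(num_features, dtype=np.float32))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        C = xd.shape[1]
        gamma, beta = self.gamma, self.beta
        if self.training:
            mean = xd.mean(axis=(0, 2, 3))
            var = xd.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xd - mean[None, :, None, None]) * inv[None, :, None, None]
        out_data = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]
        training = self.training

        def backward(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gs = g * gamma.data[None, :, None, None]
                if training:
                    n = g.shape[0] * g.shape[2] * g.shape[3]
                    gmean = gs.mean(axis=(0, 2, 3), keepdims=True)
                    gxhat_mean = (gs * xhat).mean(axis=(0, 2, 3), keepdims=True)
                    gx = (gs - gmean - xhat * gxhat_mean) * inv[None, :, None, None]
                else:
                    gx = gs * inv[None, :, None, None]
                x._accum(gx)

        return Tensor._from_op(out_data.astype(xd.dtype, copy=False),
                               (x, gamma, beta), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Spatial mean per channel: (B,C,H,W) -> (B,C)."""
    if x.ndim != 4 or x.shape[2] * x.shape[3] == 0:
        raise ValueError("global_avg_pool expects a non-empty B,C,H,W tensor")
    return x.mean(axis=(2, 3))


def global_max_pool(x: Tensor) -> Tensor:
    """Spatial max per channel: (B,C,H,W) -> (B,C)."""
    if x.ndim != 4 or x.shape[2] * x.shape[3] == 0:
        raise ValueError("global_max_pool expects a non-empty B,C,H,W tensor")
    return x.reshape(x.shape[0], x.shape[1], -1).max(axis=2)
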