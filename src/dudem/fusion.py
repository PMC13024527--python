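"""Fusion of the convolutional map Fc and capsule map Fv.

The full model uses a learned channel-attention gate in the squeeze-
excitation pattern:

    alpha = sigmoid(MLP(GAP([Fc; Fv])))          # per-channel, in (0,1)
    F_fuse = alpha * Fc + (1 - alpha) * phi(Fv)

where ``phi`` is a bias-free 1x1 convolution aligning Fv's channels to Fc's
and the MLP is a two-layer bottleneck (reduction 16 by default).  Three
diagnostic/ablation variants share the same output contract (spatial dims and
channel count of Fc): a fixed scalar convex combination, elementwise
summation, and concatenation followed by a 1x1 reduction.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, Module, Conv2d, Linear, Sequential, ReLU, concat, \
    global_avg_pool, global_max_pool

__all__ = ["ChannelAlign", "AttentionFusion", "scalar_fusion",
           "SumFusion", "ConcatFusion"]


def _check_spatial(fc: Tensor, fv: Tensor) -> None:
    if fc.shape[2:] != fv.shape[2:]:
        raise ValueError(f"spatial mismatch: Fc {fc.shape[2:]} vs Fv {fv.shape[2:]}")


class ChannelAlign(Module):
    """phi: bias-free 1x1 convolution Cv -> Cc."""

    def __init__(self, in_ch: int, out_ch: int, rng=None):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, 1, rng=rng, bias=False)

    def forward(self, fv: Tensor) -> Tensor:
        return self.conv(fv)


class AttentionFusion(Module):
    """Learned channel gate over concatenated global descriptors."""

    def __init__(self, c_conv: int, c_caps: int, reduction: int = 16,
                 seed: int = 0, pool: str = "avg"):
        super().__init__()
        if reduction < 1:
            raise ValueError("mlp reduction must be >= 1")
        rng = np.random.default_rng(seed)
        hidden = max(1, c_conv // reduction)
        self.align = ChannelAlign(c_caps, c_conv, rng=rng)
        self.mlp = Sequential(Linear(c_conv + c_caps, hidden, rng=rng),
                              ReLU(),
                              Linear(hidden, c_conv, rng=rng))
        self.pool = pool
        self.last_alpha = None

    def forward(self, fc: Tensor, fv: Tensor) -> Tensor:
        _check_spatial(fc, fv)
        pool = global_max_pool if self.pool == "max" else global_avg_pool
        desc = pool(concat([fc, fv], axis=1))
        alpha = self.mlp(desc).sigmoid()                    # B, Cc in (0,1)
        self.last_alpha = alpha.data
        a = alpha.reshape(alpha.shape[0], alpha.shape[1], 1, 1)
        return a * fc + (1.0 - a) * self.align(fv)


def scalar_fusion(fc: Tensor, fv_aligned: Tensor, alpha: float) -> Tensor:
    """Fixed convex combination alpha*Fc + (1-alpha)*Fv (channel-aligned Fv)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    fc = fc if isinstance(fc, Tensor) else Tensor(fc)
    fv_aligned = fv_aligned if isinstance(fv_aligned, Tensor) else Tensor(fv_aligned)
    _check_spatial(fc, fv_aligned)
    if fc.shape[1] != fv_aligned.shape[1]:
        raise ValueError("scalar fusion requires channel-aligned inputs")
    return fc * alpha + fv_aligned * (1.0 - alpha)


class SumFusion(Module):
    """Ablation variant: Fc + phi(Fv)."""

    def __init__(self, c_conv: int, c_caps: int, seed: int = 0):
        super().__init__()
        self.align = ChannelAlign(c_caps, c_conv, rng=np.random.default_rng(seed))

    def forward(self, fc: Tensor, fv: Tensor) -> Tensor:
        _check_spatial(fc, fv)
        return fc + self.align(fv)


class ConcatFusion(Module):
    """Ablation variant: 1x1-reduced [Fc; phi(Fv)] back to Cc channels."""

    def __init__(self, c_conv: int, c_caps: int, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.align = ChannelAlign(c_caps, c_conv, rng=rng)
        self.reduce = Conv2d(2 * c_conv, c_conv, 1, rng=rng, bias=False)

    def forward(self, fc: Tensor, fv: Tensor) -> Tensor:
        _check_spatial(fc, fv)
        return self.reduce(concat([fc, self.align(fv)], axis=1))
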