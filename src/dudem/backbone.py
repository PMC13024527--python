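"""Convolutional branch: a ResNet50-topology feature extractor.

The stem is a 7x7 stride-2 convolution followed by a 3x3 stride-2 max pool;
four stages of bottleneck residual blocks (3, 4, 6, 3 of them) each halve the
spatial resolution (except stage 1), for a total spatial reduction of x32.
The canonical v1 ordering (conv -> BN -> ReLU, post-activation residual) is
used.

At the full width (``width_multiplier=1.0``) the final map has 2048 channels;
a reduced desk profile (``width_multiplier=0.25`` -> 512 channels) makes CPU
training practical, and the class reports its own channel count ``out_channels``
so downstream modules never assume 2048.

Weights are randomly initialized from a seeded generator.  There is a
``pretrained`` flag in the run config for users who supply their own
checkpoint; no weights are downloaded.
"""

from __future__ import annotations

import numpy as np

from .nn import (
    Module, Sequential, Conv2d, BatchNorm2d, ReLU, MaxPool2d,
    Tensor, global_avg_pool,
)

__all__ = ["ResNetBackbone", "backbone_output_shape", "check_image_batch"]

_STAGE_BLOCKS = (3, 4, 6, 3)
_STAGE_WIDTHS = (64, 128, 256, 512)   # inner bottleneck widths at multiplier 1
_EXPANSION = 4


def check_image_batch(x: np.ndarray) -> None:
    """Validate the B,3,H,W contract: 3 channels, H and W >= 32."""
    if x.ndim != 4:
        raise ValueError(f"expected a B,C,H,W batch, got ndim={x.ndim}")
    if x.shape[1] != 3:
        raise ValueError(f"expected 3 input channels, got {x.shape[1]}")
    if x.shape[2] < 32 or x.shape[3] < 32:
        raise ValueError(f"input {x.shape[2]}x{x.shape[3]} below the 32-pixel minimum")


def _conv_out(size: int, kernel: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - kernel) // stride + 1


def backbone_output_shape(h: int, w: int) -> tuple:
    """Spatial shape oracle: floor arithmetic of the stem + four stages."""
    for k, s, p in ((7, 2, 3), (3, 2, 1)):          # stem conv, stem pool
        h, w = _conv_out(h, k, s, p), _conv_out(w, k, s, p)
    for _ in range(3):                               # stages 2-4 stride 2
        h, w = _conv_out(h, 3, 2, 1), _conv_out(w, 3, 2, 1)
    return h, w


class Bottleneck(Module):
    def __init__(self, in_ch, width, stride, rng):
        super().__init__()
        out_ch = width * _EXPANSION
        self.conv1 = Conv2d(in_ch, width, 1, rng=rng)
        self.bn1 = BatchNorm2d(width)
        self.conv2 = Conv2d(width, width, 3, stride=stride, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(width)
        self.conv3 = Conv2d(width, out_ch, 1, rng=rng)
        self.bn3 = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng)
            self.down_bn = BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        identity = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (out + identity).relu()


class ResNetBackbone(Module):
    """Feature extractor exposing the stage-4 map and its pooled vector.

    Parameters
    ----------
    width_multiplier : scales every channel width; 1.0 gives the canonical
        2048-channel output, 0.25 the 512-channel desk profile.
    seed : RNG seed for weight initialization.
    """

    def __init__(self, width_multiplier: float = 1.0, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.width_multiplier = width_multiplier
        stem = max(8, int(round(64 * width_multiplier)))
        self.conv1 = Conv2d(3, stem, 7, stride=2, padding=3, rng=rng)
        self.bn1 = BatchNorm2d(stem)
        self.maxpool = MaxPool2d(3, 2, 1)
        stages = []
        in_ch = stem
        for si, (blocks, base_w) in enumerate(zip(_STAGE_BLOCKS, _STAGE_WIDTHS)):
            width = max(4, int(round(base_w * width_multiplier)))
            stage = []
            for bi in range(blocks):
                stride = 2 if (si > 0 and bi == 0) else 1
                stage.append(Bottleneck(in_ch, width, stride, rng))
                in_ch = width * _EXPANSION
            stages.append(Sequential(*stage))
        self.stages = stages
        self.out_channels = in_ch

    def extract_features(self, x) -> Tensor:
        """Image batch (B,3,H,W) -> stage-4 feature map (B, Cc, H/32, W/32)."""
        if isinstance(x, Tensor):
            check_image_batch(x.data)
        else:
            check_image_batch(np.asarray(x))
            x = Tensor(x)
        out = self.bn1(self.conv1(x)).relu()
        out = self.maxpool(out)
        for stage in self.stages:
            out = stage(out)
        return out

    forward = extract_features

    @staticmethod
    def global_pool(fm: Tensor) -> Tensor:
        """Per-channel spatial mean of a feature map: (B,C,H,W) -> (B,C)."""
        return global_avg_pool(fm)
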