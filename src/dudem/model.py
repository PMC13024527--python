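"""Full dual-branch network and its seven ablation variants.

``DuDeM`` wires the pieces end to end: the convolutional branch produces the
local-texture map Fc, the capsule branch the pose-aware map Fv, a fusion
module combines them, and two heads emit class probabilities and a
normalized bounding box.

Variants (the ablation grid):

==  ==========================================================
A0  full model (attention fusion, two-layer FC head, avg pools)
A1  remove the capsule branch (heads directly on Fc)
A2  remove the convolutional branch (capsule branch fed by a small
    two-layer conv stem from the image; heads on Fv)
A3  replace attention fusion with elementwise summation
A4  replace attention fusion with concatenation + 1x1 reduction
A5  replace the head/gate global average pools with global max pools
A6  replace the two-layer FC head with a single linear layer
==  ==========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nn import Tensor, Module, Conv2d, BatchNorm2d, Sequential, ReLU, no_grad
from .backbone import ResNetBackbone, check_image_batch
from .capsule import CapsuleBranch
from .fusion import AttentionFusion, SumFusion, ConcatFusion, scalar_fusion
from .heads import ClassificationHead, BoxHead

__all__ = ["ModelConfig", "DuDeM", "VariantSpec", "VARIANTS", "build_variant",
           "desk_config", "full_config", "tiny_config"]


@dataclass
class ModelConfig:
    k_classes: int = 3
    image_size: int = 224
    width_multiplier: float = 1.0
    use_backbone: bool = True
    use_capsules: bool = True
    fusion: str = "attention"           # attention | scalar | sum | concat
    fusion_alpha: float = 0.5           # scalar mode only
    mlp_reduction: int = 16
    caps_per_cell: int = 8
    d_primary: int = 8
    d_category: int = 16
    routing_iters: int = 3
    respatialize: str = "broadcast"
    capsule_source: str = "backbone"    # backbone | image
    head_depth: int = 2
    pool: str = "avg"                   # avg | max (head + gate pools)
    seed: int = 0


def full_config(**kw) -> ModelConfig:
    return ModelConfig(**kw)


def desk_config(**kw) -> ModelConfig:
    """Reduced profile for CPU-scale experiments: 64x64 input, width x0.25."""
    base = dict(image_size=64, width_multiplier=0.25, mlp_reduction=8)
    base.update(kw)
    return ModelConfig(**base)


def tiny_config(**kw) -> ModelConfig:
    """Smallest runnable profile (32x32 input), for smoke tests and repeats."""
    base = dict(image_size=32, width_multiplier=0.125, mlp_reduction=4,
                caps_per_cell=4, d_primary=4, d_category=8)
    base.update(kw)
    return ModelConfig(**base)


class ImageCapsuleStem(Module):
    """Two 3x3 stride-2 convolutions feeding the capsule branch from pixels."""

    def __init__(self, width: int, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        mid = max(8, width // 2)
        self.net = Sequential(
            Conv2d(3, mid, 3, stride=2, padding=1, rng=rng), BatchNorm2d(mid), ReLU(),
            Conv2d(mid, width, 3, stride=2, padding=1, rng=rng), BatchNorm2d(width), ReLU(),
        )
        self.out_channels = width

    def forward(self, x):
        return self.net(x)


class DuDeM(Module):
    """Dual-branch lesion classifier + localizer."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        if not (cfg.use_backbone or cfg.use_capsules):
            raise ValueError("at least one branch must be enabled")
        self.cfg = cfg
        seed = cfg.seed
        if cfg.use_backbone:
            self.backbone = ResNetBackbone(cfg.width_multiplier, seed=seed)
            cc = self.backbone.out_channels
            fm_hw = (cfg.image_size // 32, cfg.image_size // 32)
        else:
            self.backbone = None
            cc = None
            fm_hw = None

        if cfg.use_capsules:
            if cfg.capsule_source == "image" or not cfg.use_backbone:
                stem_w = max(16, int(round(64 * cfg.width_multiplier)))
                self.capsule_stem = ImageCapsuleStem(stem_w, seed=seed + 1)
                caps_in = self.capsule_stem.out_channels
                caps_hw = (cfg.image_size // 4, cfg.image_size // 4)
            else:
                self.capsule_stem = None
                caps_in = cc
                caps_hw = fm_hw
            self.capsules = CapsuleBranch(
                caps_in, cfg.k_classes, caps_hw,
                caps_per_cell=cfg.caps_per_cell, d_primary=cfg.d_primary,
                d_category=cfg.d_category, routing_iters=cfg.routing_iters,
                respatialize=cfg.respatialize, seed=seed + 2)
            cv = self.capsules.out_channels
        else:
            self.capsule_stem = None
            self.capsules = None
            cv = None

        if cfg.use_backbone and cfg.use_capsules:
            if cfg.fusion == "attention":
                self.fusion = AttentionFusion(cc, cv, reduction=cfg.mlp_reduction,
                                              seed=seed + 3, pool=cfg.pool)
            elif cfg.fusion == "sum":
                self.fusion = SumFusion(cc, cv, seed=seed + 3)
            elif cfg.fusion == "concat":
                self.fusion = ConcatFusion(cc, cv, seed=seed + 3)
            elif cfg.fusion == "scalar":
                from .fusion import ChannelAlign
                self.fusion = None
                self.scalar_align = ChannelAlign(cv, cc,
                                                 rng=np.random.default_rng(seed + 3))
            else:
                raise ValueError(f"unknown fusion mode {cfg.fusion!r}")
            head_ch = cc
        else:
            self.fusion = None
            head_ch = cc if cfg.use_backbone else cv

        self.classifier = ClassificationHead(head_ch, cfg.k_classes,
                                             depth=cfg.head_depth,
                                             pool=cfg.pool, seed=seed + 4)
        self.box_head = BoxHead(head_ch, pool=cfg.pool, seed=seed + 5)
        self.head_channels = head_ch

    # -- forward --------------------------------------------------------------
    def fused_map(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        fc = self.backbone.extract_features(x) if self.backbone is not None else None
        if self.capsules is not None:
            caps_in = self.capsule_stem(x) if self.capsule_stem is not None else fc
            fv = self.capsules(caps_in)
        else:
            fv = None
        if fc is not None and fv is not None:
            if cfg.fusion == "scalar":
                return scalar_fusion(fc, self.scalar_align(fv), cfg.fusion_alpha)
            return self.fusion(fc, fv)
        return fc if fc is not None else fv

    def forward(self, x):
        if not isinstance(x, Tensor):
            check_image_batch(np.asarray(x))
            x = Tensor(np.ascontiguousarray(x))
        fused = self.fused_map(x)
        probs = self.classifier(fused)
        boxes = self.box_head(fused)
        return probs, boxes

    def predict(self, x):
        """Inference-mode forward: returns (probs, boxes) ndarrays."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                probs, boxes = self.forward(x)
        finally:
            self.train(was_training)
        return probs.data, boxes.data


@dataclass
class VariantSpec:
    id: str
    description: str
    overrides: dict = field(default_factory=dict)


VARIANTS = {
    "A0": VariantSpec("A0", "full model", {}),
    "A1": VariantSpec("A1", "remove capsule branch", {"use_capsules": False}),
    "A2": VariantSpec("A2", "remove convolutional branch",
                      {"use_backbone": False}),
    "A3": VariantSpec("A3", "summation fusion", {"fusion": "sum"}),
    "A4": VariantSpec("A4", "concatenation fusion", {"fusion": "concat"}),
    "A5": VariantSpec("A5", "max pooling before heads and gate", {"pool": "max"}),
    "A6": VariantSpec("A6", "single-layer FC head", {"head_depth": 1}),
}


def build_variant(variant, base_config: ModelConfig) -> DuDeM:
    """Materialize an ablation variant from a base configuration."""
    if isinstance(variant, str):
        if variant not in VARIANTS:
            raise KeyError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")
        variant = VARIANTS[variant]
    cfg = replace(base_config, **variant.overrides)
    return DuDeM(cfg)
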