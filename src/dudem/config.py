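"""YAML run configuration.

A run config has up to five blocks, all optional::

    model:   {k_classes: 3, image_size: 64, width_multiplier: 0.25, ...}
    capsule: {caps_per_cell: 8, d_primary: 8, d_category: 16,
              routing_iters: 3, respatialize: broadcast, source: backbone}
    fusion:  {mode: attention, mlp_reduction: 16, alpha: 0.5}
    loss:    {lambda: 1.0, class_weights: auto}
    train:   {epochs: 100, batch_size: 32, lr_init: 0.005, ...}
    data:    {n_images: 2000, image_size: 64, class_probs: [0.56, 0.33, 0.11], ...}

Unknown keys raise, so typos fail fast.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .model import ModelConfig
from .training import TrainConfig
from .synthetic import SyntheticSpec

__all__ = ["RunConfig", "load_run_config"]

_CAPSULE_KEYS = {"caps_per_cell": "caps_per_cell", "d_primary": "d_primary",
                 "d_category": "d_category", "routing_iters": "routing_iters",
                 "respatialize": "respatialize", "source": "capsule_source"}
_FUSION_KEYS = {"mode": "fusion", "mlp_reduction": "mlp_reduction",
                "alpha": "fusion_alpha"}
_LOSS_KEYS = {"lambda": "lam", "class_weights": "class_weighting"}


class RunConfig:
    def __init__(self, model: ModelConfig, train: TrainConfig, data: SyntheticSpec):
        self.model = model
        self.train = train
        self.data = data


def _build(cls, block: dict, what: str):
    valid = {f.name for f in fields(cls)}
    bad = set(block) - valid
    if bad:
        raise KeyError(f"unknown {what} config keys: {sorted(bad)}")
    return cls(**block)


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"model", "capsule", "fusion", "loss", "train", "data"}
    bad = set(raw) - known
    if bad:
        raise KeyError(f"unknown config blocks: {sorted(bad)}")
    model_kw = dict(raw.get("model", {}))
    for src, dst in _CAPSULE_KEYS.items():
        if src in raw.get("capsule", {}):
            model_kw[dst] = raw["capsule"][src]
    for src, dst in _FUSION_KEYS.items():
        if src in raw.get("fusion", {}):
            model_kw[dst] = raw["fusion"][src]
    train_kw = dict(raw.get("train", {}))
    for src, dst in _LOSS_KEYS.items():
        if src in raw.get("loss", {}):
            train_kw[dst] = raw["loss"][src]
    data_kw = dict(raw.get("data", {}))
    if "class_probs" in data_kw:
        data_kw["class_probs"] = tuple(data_kw["class_probs"])
    return RunConfig(_build(ModelConfig, model_kw, "model"),
                     _build(TrainConfig, train_kw, "train"),
                     _build(SyntheticSpec, data_kw, "data"))
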