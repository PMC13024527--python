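"""Ablation harness: train each variant under identical settings and report
test-accuracy degradation in percentage points relative to the full model A0
(fixed at zero), mirroring the usual ablation-table layout."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .model import ModelConfig, VARIANTS, build_variant
from .synthetic import SyntheticSpec, generate_arrays
from .training import TrainConfig, fit, evaluate_model, split_indices

__all__ = ["run_variant", "run_ablation"]


def run_variant(variant_id: str, model_cfg: ModelConfig, train_cfg: TrainConfig,
                data) -> dict:
    """Train one variant; returns test metrics and bookkeeping."""
    images, labels, boxes, has_box = data
    tr, va, te = split_indices(len(images), train_cfg, seed=train_cfg.seed)
    trv = np.concatenate([tr, va])
    model = build_variant(variant_id, model_cfg)
    hist = fit(model, images[trv], labels[trv], boxes[trv], has_box[trv],
               cfg=train_cfg)
    cm, rep = evaluate_model(model, images[te], labels[te],
                             normalization=hist["normalization"])
    return {"variant": variant_id,
            "description": VARIANTS[variant_id].description,
            "params": model.num_parameters(),
            "test_accuracy": float(np.trace(cm) / cm.sum()),
            "sensitivity": rep.sensitivity,
            "specificity": rep.specificity,
            "auc": rep.auc,
            "epochs_run": len(hist["epoch"])}


def run_ablation(variant_ids, model_cfg: ModelConfig, train_cfg: TrainConfig,
                 data_spec: SyntheticSpec) -> pd.DataFrame:
    """Run the listed variants on one shared synthetic dataset.

    The returned table carries ``degradation_pp`` = (A0 accuracy - variant
    accuracy) x 100; A0, when present, is 0 by construction.
    """
    data = generate_arrays(data_spec)
    rows = [run_variant(vid, model_cfg, train_cfg, data) for vid in variant_ids]
    df = pd.DataFrame(rows)
    if "A0" in set(df["variant"]):
        base = float(df.loc[df["variant"] == "A0", "test_accuracy"].iloc[0])
    else:
        base = float(df["test_accuracy"].max())
    df["degradation_pp"] = (base - df["test_accuracy"]) * 100.0
    return df
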