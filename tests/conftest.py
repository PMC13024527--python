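"""Shared fixtures.

The expensive fixture is a set of trained tiny-profile models (32x32 input,
three seeds) reused by the robustness and branch-contribution trend tests so
the suite trains each network only once.
"""

from __future__ import annotations

import numpy as np
import pytest

from dudem.model import DuDeM, build_variant, tiny_config
from dudem.synthetic import SyntheticSpec, generate_arrays
from dudem.training import TrainConfig, fit, split_indices, evaluate_model

TINY_SEEDS = (1, 2, 3)
TINY_N = 800


def train_tiny_variant(variant_id: str, seed: int, data=None):
    """Train one tiny-profile variant on a fresh seeded synthetic dataset."""
    spec = SyntheticSpec(n_images=TINY_N, image_size=32, seed=seed)
    images, labels, boxes, has_box = data if data is not None else generate_arrays(spec)
    cfg = TrainConfig(epochs=35, seed=seed, stop_at_val_metric=0.95)
    tr, va, te = split_indices(len(images), cfg, seed=seed)
    trv = np.concatenate([tr, va])
    model = build_variant(variant_id, tiny_config(seed=seed))
    hist = fit(model, images[trv], labels[trv], boxes[trv], has_box[trv], cfg=cfg)
    return {"model": model, "history": hist, "images": images, "labels": labels,
            "test_idx": te, "seed": seed}


@pytest.fixture(scope="session")
def tiny_runs():
    """Trained tiny A0 and A1 models for three seeds, with their datasets."""
    runs = {}
    for seed in TINY_SEEDS:
        spec = SyntheticSpec(n_images=TINY_N, image_size=32, seed=seed)
        data = generate_arrays(spec)
        runs[seed] = {
            "A0": train_tiny_variant("A0", seed, data=data),
            "A1": train_tiny_variant("A1", seed, data=data),
        }
    return runs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
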