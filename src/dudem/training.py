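"""Training loop, dataset splitting, checkpointing and repeat-run summaries.

The protocol: Adam (beta1 = 0.9, weight decay 1e-4), batch size 32, initial
learning rate 0.005 decayed by per-epoch cosine annealing to 1e-5 over the
epoch budget, early stopping when the validation metric fails to improve for
``patience`` consecutive epochs, best-validation weights retained.  Data is
split 8:2 into train/test, with 10% of the training portion held out for
validation; when a grouping column (e.g. patient id) is present the split is
group-aware.  Repeated runs with distinct seeds are summarized as
mean +/- standard deviation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .nn import Tensor, Adam
from .model import DuDeM, ModelConfig
from .heads import (cross_entropy_loss, bbox_regression_loss, total_loss,
                    inverse_frequency_weights)
from .evaluation import confusion, binary_collapse, binary_metrics

__all__ = ["TrainConfig", "cosine_lr", "split_indices", "fit",
           "save_checkpoint", "load_checkpoint", "evaluate_model",
           "lesion_scores", "repeat_runs"]


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    lr_init: float = 0.005
    lr_final: float = 1e-5
    beta1: float = 0.9
    weight_decay: float = 1e-4
    patience: int = 10
    lam: float = 1.0                    # box-loss weight
    class_weighting: str = "auto"       # auto | off
    val_fraction: float = 0.10          # of the training portion
    test_fraction: float = 0.20
    val_metric: str = "accuracy"        # accuracy | loss
    stop_at_val_metric: float | None = None   # optional compute-saving stop
    augment: bool = True                # random hflip + 4-px-padded random crop
    crop_padding: int = 4
    photometric_jitter: float = 0.2     # +/- brightness/contrast factor range
    seed: int = 0

    def __post_init__(self):
        if self.lr_final >= self.lr_init:
            raise ValueError("lr_final must be < lr_init")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def cosine_lr(epoch: int, cfg: TrainConfig) -> float:
    """Per-epoch cosine annealing from lr_init to lr_final."""
    if not 0 <= epoch <= cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs}]")
    return cfg.lr_final + 0.5 * (cfg.lr_init - cfg.lr_final) * (
        1.0 + math.cos(math.pi * epoch / cfg.epochs))


def split_indices(n: int, cfg: TrainConfig, seed: int, groups=None):
    """(train, val, test) index arrays; group-aware when groups are given."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5917]))
    if groups is not None:
        groups = np.asarray(groups)
        uniq = rng.permutation(np.unique(groups))
        n_test_g = max(1, int(round(len(uniq) * cfg.test_fraction)))
        test_g = set(uniq[:n_test_g])
        trainval = np.array([i for i in range(n) if groups[i] not in test_g])
        test = np.array([i for i in range(n) if groups[i] in test_g])
        tv_groups = groups[trainval]
        uniq_tv = rng.permutation(np.unique(tv_groups))
        n_val_g = max(1, int(round(len(uniq_tv) * cfg.val_fraction)))
        val_g = set(uniq_tv[:n_val_g])
        val = trainval[[g in val_g for g in tv_groups]]
        train = trainval[[g not in val_g for g in tv_groups]]
        return train, val, test
    perm = rng.permutation(n)
    n_test = int(round(n * cfg.test_fraction))
    test, trainval = perm[:n_test], perm[n_test:]
    n_val = int(round(len(trainval) * cfg.val_fraction))
    val, train = trainval[:n_val], trainval[n_val:]
    return train, val, test


def _augment_batch(x, boxes, has_box, rng, pad: int = 4, jitter: float = 0.0):
    """Random hflip, padded random crop, and photometric jitter on raw pixels;
    boxes move coherently with the geometry."""
    x = x.copy()
    boxes = boxes.copy()
    B, _, H, W = x.shape
    flip = rng.random(B) < 0.5
    x[flip] = x[flip][..., ::-1]
    boxes[flip & has_box, 0] = 1.0 - boxes[flip & has_box, 0]
    if jitter:
        bright = rng.uniform(1 - jitter, 1 + jitter, size=(B, 1, 1, 1))
        contr = rng.uniform(1 - jitter, 1 + jitter, size=(B, 1, 1, 1))
        means = x.mean(axis=(1, 2, 3), keepdims=True)
        x = np.clip((x * bright - means) * contr + means, 0.0, 1.0
                    ).astype(np.float32)
    if pad:
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="edge")
        offs = rng.integers(0, 2 * pad + 1, size=(B, 2))
        for i in range(B):
            dy, dx = offs[i]
            x[i] = xp[i, :, dy:dy + H, dx:dx + W]
            if has_box[i]:
                cx = boxes[i, 0] + (pad - dx) / W
                cy = boxes[i, 1] + (pad - dy) / H
                boxes[i, 0] = np.clip(cx, boxes[i, 2] / 2, 1 - boxes[i, 2] / 2)
                boxes[i, 1] = np.clip(cy, boxes[i, 3] / 2, 1 - boxes[i, 3] / 2)
    return x, boxes


def _normalization_stats(images: np.ndarray):
    mean = images.mean(axis=(0, 2, 3))
    std = images.std(axis=(0, 2, 3)) + 1e-6
    return mean.astype(np.float32), std.astype(np.float32)


def _normalize(images, mean, std):
    return ((images - mean[None, :, None, None]) / std[None, :, None, None]
            ).astype(np.float32)


def _accuracy(model: DuDeM, images, labels, batch: int = 64) -> float:
    preds = predict_labels(model, images, batch=batch)
    return float((preds == labels).mean())


def predict_probs(model: DuDeM, images, batch: int = 64) -> np.ndarray:
    out = []
    for i in range(0, len(images), batch):
        probs, _ = model.predict(images[i:i + batch])
        out.append(probs)
    return np.concatenate(out, axis=0)


def predict_labels(model: DuDeM, images, batch: int = 64) -> np.ndarray:
    return predict_probs(model, images, batch=batch).argmax(axis=1)


def lesion_scores(model: DuDeM, images, batch: int = 64) -> np.ndarray:
    """Binary lesion score: 1 - P(normal)."""
    return 1.0 - predict_probs(model, images, batch=batch)[:, 0]


def fit(model: DuDeM, images, labels, boxes=None, has_box=None,
        cfg: TrainConfig | None = None, val_data=None, verbose: bool = False):
    """Train ``model`` in place; returns a history dict.

    ``images``/``labels`` (and optional boxes) are the *training* portion; a
    validation split of ``cfg.val_fraction`` is carved out internally unless
    ``val_data=(val_images, val_labels)`` is supplied.  Inputs are normalized
    with per-channel statistics computed from the training portion (stored in
    the history for checkpointing).
    """
    cfg = cfg or TrainConfig()
    labels = np.asarray(labels)
    if len(images) == 0:
        raise ValueError("empty training data")
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain at least two classes")
    if boxes is None:
        boxes = np.zeros((len(images), 4), dtype=np.float32)
    if has_box is None:
        has_box = np.zeros(len(images), dtype=bool)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7EA1]))
    if val_data is None:
        n_val = max(1, int(round(len(images) * cfg.val_fraction)))
        perm = rng.permutation(len(images))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
    else:
        tr_idx = np.arange(len(images))
        val_idx = None

    mean, std = _normalization_stats(images[tr_idx])
    x_tr = np.asarray(images)[tr_idx]        # kept raw; normalized per batch
    y_tr = labels[tr_idx]
    b_tr = np.asarray(boxes)[tr_idx]
    hb_tr = np.asarray(has_box)[tr_idx]
    if val_data is None:
        x_val = _normalize(images[val_idx], mean, std)
        y_val = labels[val_idx]
    else:
        x_val = _normalize(val_data[0], mean, std)
        y_val = np.asarray(val_data[1])

    if cfg.class_weighting == "auto":
        weights = inverse_frequency_weights(y_tr, model.cfg.k_classes)
    else:
        weights = None

    opt = Adam(model.parameters(), lr=cfg.lr_init, beta1=cfg.beta1,
               weight_decay=cfg.weight_decay)
    history = {"epoch": [], "train_loss": [], "val_metric": [], "lr": [],
               "normalization": {"mean": mean.tolist(), "std": std.tolist()},
               "config": asdict(cfg)}
    best_metric = -np.inf
    best_state = None
    best_epoch = -1
    n = len(x_tr)
    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg)
        opt.lr = lr
        model.train()
        order = rng.permutation(n)
        tot_loss, n_batches = 0.0, 0
        for s in range(0, n, cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            xb, bb = x_tr[idx], b_tr[idx]
            if cfg.augment:
                xb, bb = _augment_batch(xb, bb, hb_tr[idx], rng,
                                        pad=cfg.crop_padding,
                                        jitter=cfg.photometric_jitter)
            xb = _normalize(xb, mean, std)
            probs, pred_boxes = model(Tensor(np.ascontiguousarray(xb)))
            cls = cross_entropy_loss(y_tr[idx], probs, class_weights=weights)
            reg = bbox_regression_loss(pred_boxes, bb, hb_tr[idx])
            lb = total_loss(cls, reg, lam=cfg.lam)
            opt.zero_grad()
            lb.total.backward()
            opt.step()
            tot_loss += float(lb.total.data)
            n_batches += 1
        if cfg.val_metric == "loss":
            val_probs = predict_probs(model, x_val)
            vloss = float(cross_entropy_loss(y_val, Tensor(val_probs)).data)
            val_metric = -vloss
        else:
            val_metric = _accuracy(model, x_val, y_val)
        history["epoch"].append(epoch)
        history["train_loss"].append(tot_loss / max(n_batches, 1))
        history["val_metric"].append(val_metric)
        history["lr"].append(lr)
        if verbose:
            print(f"epoch {epoch:3d} lr {lr:.5f} loss {tot_loss / n_batches:.4f} "
                  f"val {val_metric:.4f}")
        if val_metric > best_metric:
            best_metric = val_metric
            best_epoch = epoch
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
        if cfg.stop_at_val_metric is not None and val_metric >= cfg.stop_at_val_metric:
            break
        if epoch - best_epoch >= cfg.patience:
            break
    if best_state is not None:
        model.load_state_arrays(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_metric"] = float(best_metric)
    return history


# -- checkpoints --------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(path, model: DuDeM, history=None):
    meta = {"version": CHECKPOINT_VERSION,
            "model_config": asdict(model.cfg),
            "normalization": (history or {}).get("normalization")}
    arrays = model.state_arrays()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path):
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        cfg = ModelConfig(**meta["model_config"])
        model = DuDeM(cfg)
        model.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
    return model, meta


def evaluate_model(model: DuDeM, images, labels, normalization=None):
    """Multi-class confusion + binary lesion-vs-normal metrics (argmax route)."""
    if normalization is not None:
        mean = np.asarray(normalization["mean"], dtype=np.float32)
        std = np.asarray(normalization["std"], dtype=np.float32)
        images = _normalize(images, mean, std)
    labels = np.asarray(labels)
    k = model.cfg.k_classes
    probs = predict_probs(model, images)
    preds = probs.argmax(axis=1)
    cm = confusion(labels, preds, k)
    lesion_classes = list(range(1, k))
    rep = binary_metrics(binary_collapse(cm, lesion_classes))
    from .evaluation import roc_auc
    scores = 1.0 - probs[:, 0]
    y_bin = labels != 0
    if y_bin.any() and not y_bin.all():
        rep.auc = roc_auc(scores, y_bin)
    return cm, rep


def repeat_runs(run_fn, seeds):
    """Run ``run_fn(seed) -> dict of scalars`` and summarize mean +/- sd."""
    rows = [run_fn(s) for s in seeds]
    df = pd.DataFrame(rows)
    return df, df.agg(["mean", "std"])
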