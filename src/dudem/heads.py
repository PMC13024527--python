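"""Classification / bounding-box heads and the composite training objective.

The classifier applies global pooling to the fused map and a fully connected
head (two-layer with ReLU by default; single-layer for the shallow-head
ablation), ending in a softmax.  The box head regresses a normalized
(cx, cy, w, h) through a sigmoid so every component lies in [0, 1].

The objective is

    L_total = L_classification + lambda * L_regression

with weighted cross-entropy for classification and a Smooth-L1 (Huber)
penalty, averaged over the four box parameters of lesion images only —
lesion-free images carry no box supervision.  Smooth-L1 is implemented
symmetrically, 0.5 x^2 for |x| < 1 and |x| - 0.5 otherwise, which keeps the
loss even and continuously differentiable at |x| = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, Module, Linear, ReLU, Sequential, global_avg_pool, \
    global_max_pool

__all__ = ["ClassificationHead", "BoxHead", "cross_entropy_loss", "smooth_l1",
           "bbox_regression_loss", "total_loss", "LossBreakdown",
           "inverse_frequency_weights"]


@dataclass
class LossBreakdown:
    total: Tensor
    classification: Tensor
    regression: Tensor
    lam: float


class ClassificationHead(Module):
    """Pool -> FC head -> softmax probabilities."""

    def __init__(self, in_ch: int, k_classes: int, depth: int = 2,
                 pool: str = "avg", seed: int = 0):
        super().__init__()
        if k_classes < 2:
            raise ValueError("need at least 2 classes")
        if depth not in (1, 2):
            raise ValueError("head depth must be 1 or 2")
        rng = np.random.default_rng(seed)
        if depth == 2:
            hidden = max(4, in_ch // 4)
            self.fc = Sequential(Linear(in_ch, hidden, rng=rng), ReLU(),
                                 Linear(hidden, k_classes, rng=rng))
        else:
            self.fc = Linear(in_ch, k_classes, rng=rng)
        self.pool = pool

    def logits(self, fused: Tensor) -> Tensor:
        pool = global_max_pool if self.pool == "max" else global_avg_pool
        return self.fc(pool(fused))

    def forward(self, fused: Tensor) -> Tensor:
        return self.logits(fused).softmax(axis=-1)


class BoxHead(Module):
    """Pool -> linear -> sigmoid, giving (cx, cy, w, h) in [0, 1]."""

    def __init__(self, in_ch: int, pool: str = "avg", seed: int = 0):
        super().__init__()
        self.fc = Linear(in_ch, 4, rng=np.random.default_rng(seed))
        self.pool = pool

    def forward(self, fused: Tensor) -> Tensor:
        pool = global_max_pool if self.pool == "max" else global_avg_pool
        return self.fc(pool(fused)).sigmoid()


def inverse_frequency_weights(labels: np.ndarray, k_classes: int) -> np.ndarray:
    """Per-class weights proportional to 1/frequency, normalized to mean 1."""
    counts = np.bincount(np.asarray(labels, dtype=int), minlength=k_classes)
    counts = np.maximum(counts, 1)
    w = counts.sum() / (k_classes * counts)
    return (w / w.mean()).astype(np.float64)


def cross_entropy_loss(y_true, y_prob, class_weights=None, eps: float = 1e-12):
    """Mean weighted negative log-likelihood.

    ``y_true``: integer labels (B,) or one-hot (B, K).  ``y_prob``: probability
    rows (B, K).  Probabilities are clamped at ``eps`` before the log.
    """
    p = y_prob if isinstance(y_prob, Tensor) else Tensor(y_prob)
    y = np.asarray(y_true)
    if y.ndim == 2:
        y = y.argmax(axis=1)
    y = y.astype(int)
    B, K = p.shape
    picked = p[np.arange(B), y].clip_min(eps)
    nll = -picked.log()
    if class_weights is not None:
        w = np.asarray(class_weights, dtype=p.dtype)
        if np.any(w <= 0):
            raise ValueError("class weights must be positive")
        nll = nll * Tensor(w[y])
    return nll.mean()


def smooth_l1(x):
    """Huber penalty: 0.5 x^2 for |x| < 1, |x| - 0.5 otherwise. Elementwise."""
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
    a = t.abs()
    quad_mask = Tensor((a.data < 1.0).astype(t.dtype))
    quad = t * t * 0.5
    lin = a - 0.5
    out = quad * quad_mask + lin * (1.0 - quad_mask)
    return out if isinstance(x, Tensor) else out.data


def bbox_regression_loss(pred_boxes, true_boxes, lesion_mask):
    """Masked mean Smooth-L1 over the 4 box parameters of lesion images.

    Returns 0 for an all-normal batch (empty mask).
    """
    p = pred_boxes if isinstance(pred_boxes, Tensor) else Tensor(pred_boxes)
    mask = np.asarray(lesion_mask, dtype=bool)
    if not mask.any():
        return Tensor(np.zeros((), dtype=p.dtype))
    t = np.asarray(true_boxes, dtype=p.dtype)
    diff = p[mask] - Tensor(t[mask])
    return smooth_l1(diff).mean()


def total_loss(cls_loss, reg_loss, lam: float = 1.0) -> LossBreakdown:
    """Composite objective; the identity total = cls + lam * reg is exact."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    c = cls_loss if isinstance(cls_loss, Tensor) else Tensor(np.asarray(cls_loss, dtype=np.float64))
    r = reg_loss if isinstance(reg_loss, Tensor) else Tensor(np.asarray(reg_loss, dtype=np.float64))
    return LossBreakdown(total=c + r * lam, classification=c, regression=r, lam=lam)
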