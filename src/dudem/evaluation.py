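"""Diagnostic metrics, ROC/AUC, Youden-threshold selection, and the
perturbation-robustness report.

Conventions:

* multi-class confusion matrices have rows = ground truth, columns =
  prediction;
* the binary (lesion-vs-normal) collapse treats the lesion classes as the
  positive set;
* AUC equals the Mann–Whitney pair statistic (ties count 1/2), which also
  equals the trapezoidal area under the empirical ROC;
* the Youden-optimal threshold is chosen among the observed scores, ties
  broken toward the lowest threshold (favoring sensitivity);
* a metric with a zero denominator is reported as ``nan`` (undefined), never
  silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "confusion", "binary_collapse", "binary_metrics", "MetricsReport",
    "roc_auc", "roc_curve", "youden_threshold", "evaluate_scores",
    "perturbation_report",
    "WORKED_EXAMPLE_CONFUSION", "WORKED_EXAMPLE_CLASSES",
]

# Worked example: a published three-class gastric screening confusion matrix
# (normal / non-tumor lesion / polypoid lesion) used throughout the docs and
# tests to pin the metric definitions to printed values.
WORKED_EXAMPLE_CLASSES = ("normal", "inflammation_ulcer_bleeding_erosion",
                          "polyp_protrusion")
WORKED_EXAMPLE_CONFUSION = np.array([
    [16060, 187, 26],
    [151, 8666, 88],
    [144, 194, 2482],
], dtype=np.int64)


@dataclass
class MetricsReport:
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    accuracy: float
    youden: float
    auc: float = float("nan")
    threshold: float = float("nan")

    def as_dict(self):
        return asdict(self)


def confusion(y_true, y_pred, k_classes: int) -> np.ndarray:
    """K x K count table; rows ground truth, columns prediction."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if ((t < 0) | (t >= k_classes) | (p < 0) | (p >= k_classes)).any():
        raise ValueError(f"labels must lie in [0, {k_classes})")
    cm = np.zeros((k_classes, k_classes), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


def binary_collapse(cm: np.ndarray, positive_classes) -> np.ndarray:
    """Collapse a K x K matrix to 2x2 [[TP, FN], [FP, TN]]-free layout.

    Returns rows = (positive, negative) truth, columns = (positive, negative)
    prediction, i.e. [[TP, FN], [FP, TN]].
    """
    cm = np.asarray(cm)
    K = cm.shape[0]
    pos = sorted(set(int(c) for c in positive_classes))
    if not pos or len(pos) >= K:
        raise ValueError("positive_classes must be a non-empty proper subset")
    neg = [i for i in range(K) if i not in pos]
    tp = cm[np.ix_(pos, pos)].sum()
    fn = cm[np.ix_(pos, neg)].sum()
    fp = cm[np.ix_(neg, pos)].sum()
    tn = cm[np.ix_(neg, neg)].sum()
    return np.array([[tp, fn], [fp, tn]], dtype=np.int64)


def _safe_div(num, den):
    return float(num) / float(den) if den else float("nan")


def binary_metrics(m: np.ndarray) -> MetricsReport:
    """Threshold-free diagnostic metrics from a 2x2 [[TP,FN],[FP,TN]] table."""
    m = np.asarray(m)
    (tp, fn), (fp, tn) = m
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    prec = _safe_div(tp, tp + fp)
    acc = _safe_div(tp + tn, m.sum())
    f1 = _safe_div(2 * prec * sens, prec + sens) if not (np.isnan(prec) or np.isnan(sens)) else float("nan")
    youden = sens + spec - 1.0
    return MetricsReport(sensitivity=sens, specificity=spec, precision=prec,
                         f1=f1, accuracy=acc, youden=youden)


def roc_curve(scores, labels):
    """Empirical ROC points (fpr, tpr) sorted by threshold, for trapezoid AUC."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    order = np.argsort(-s, kind="mergesort")
    y = y[order]
    s_sorted = s[order]
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, tps / max(y.sum(), 1)]
    fpr = np.r_[0.0, fps / max((~y).sum(), 1)]
    return fpr, tpr


def roc_auc(scores, labels) -> float:
    """AUC as the Mann–Whitney statistic: P(score_pos > score_neg) + 0.5 ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    # rank-based Mann-Whitney with midranks for ties
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=float)
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    r_pos = ranks[y].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def youden_threshold(scores, labels):
    """Threshold from the observed scores maximizing J = sens + spec - 1.

    Returns ``(threshold, MetricsReport)``; predictions are score >= threshold.
    Ties in J break toward the lowest threshold (favoring sensitivity).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise ValueError("youden_threshold requires both classes present")
    best_t, best_j, best_m = None, -np.inf, None
    # ascending scan + strict improvement keeps the lowest threshold on ties
    for t in np.unique(s):
        pred = s >= t
        tp = int((pred & y).sum()); fn = int((~pred & y).sum())
        fp = int((pred & ~y).sum()); tn = int((~pred & ~y).sum())
        m = binary_metrics(np.array([[tp, fn], [fp, tn]]))
        if m.youden > best_j + 1e-12:
            best_t, best_j, best_m = float(t), m.youden, m
    best_m.threshold = best_t
    best_m.auc = roc_auc(s, y)
    return best_t, best_m


def evaluate_scores(scores, labels, threshold=None) -> MetricsReport:
    """Binary metrics at a fixed threshold (argmax caller supplies scores)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if threshold is None:
        threshold, report = youden_threshold(s, y)
        return report
    pred = s >= threshold
    tp = int((pred & y).sum()); fn = int((~pred & y).sum())
    fp = int((pred & ~y).sum()); tn = int((~pred & ~y).sum())
    report = binary_metrics(np.array([[tp, fn], [fp, tn]]))
    report.threshold = float(threshold)
    report.auc = roc_auc(s, y)
    return report


def perturbation_report(score_fn, images, labels, boxes=None, has_box=None,
                        kinds=("brightness", "contrast", "random_transform"),
                        magnitude: float = 0.2, seed: int = 0,
                        threshold: float | None = None) -> pd.DataFrame:
    """Binary lesion-vs-normal metrics on clean and perturbed copies.

    ``score_fn(images) -> lesion scores``; labels are multi-class ids with 0 =
    normal.  Deltas are in percentage points, negative meaning degradation.
    """
    from .synthetic import LabeledImage, perturb

    y_bin = np.asarray(labels) != 0
    rows = []
    clean = evaluate_scores(score_fn(images), y_bin, threshold=threshold)
    thr = clean.threshold
    rows.append({"condition": "clean", **clean.as_dict(),
                 "delta_sensitivity_pp": 0.0, "delta_specificity_pp": 0.0})
    for k, kind in enumerate(kinds):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBEEF, k]))
        pert = np.empty_like(images)
        for i in range(len(images)):
            li = LabeledImage(images[i], int(labels[i]), None)
            pert[i] = perturb(li, kind, magnitude=magnitude, rng=rng).pixels
        rep = evaluate_scores(score_fn(pert), y_bin, threshold=thr)
        rows.append({"condition": kind, **rep.as_dict(),
                     "delta_sensitivity_pp": 100 * (rep.sensitivity - clean.sensitivity),
                     "delta_specificity_pp": 100 * (rep.specificity - clean.specificity)})
    return pd.DataFrame(rows)
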