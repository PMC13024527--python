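"""Diagnostic metrics: confusion analytics, the published worked example,
AUC equivalences, Youden threshold selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dudem.evaluation import (confusion, binary_collapse, binary_metrics,
                              roc_auc, roc_curve, youden_threshold,
                              evaluate_scores, perturbation_report,
                              WORKED_EXAMPLE_CONFUSION)


def test_confusion_counts_toy_example():
    cm = confusion([0, 0, 1, 1], [0, 1, 1, 1], 2)
    assert np.array_equal(cm, [[1, 1], [0, 2]])
    assert cm.sum() == 4


def test_confusion_perfect_predictions_are_diagonal():
    y = np.array([0, 1, 2, 2, 1])
    cm = confusion(y, y, 3)
    assert np.array_equal(cm, np.diag([1, 2, 2]))


def test_confusion_rejects_out_of_range_labels():
    with pytest.raises(ValueError):
        confusion([0, 3], [0, 1], 3)


def test_worked_example_collapse_counts():
    m = binary_collapse(WORKED_EXAMPLE_CONFUSION, {1, 2})
    assert m[0, 0] == 11430      # TP
    assert m[0, 1] == 295        # FN
    assert m[1, 0] == 213        # FP
    assert m[1, 1] == 16060      # TN
    assert m[0].sum() == 11725   # lesion test images
    assert m[1].sum() == 16273   # normal test images
    assert m.sum() == 27998


def test_collapse_of_diagonal_matrix_has_no_errors():
    m = binary_collapse(np.diag([10, 5, 3]), {1, 2})
    assert m[0, 1] == 0 and m[1, 0] == 0


def test_collapse_rejects_improper_positive_sets():
    with pytest.raises(ValueError):
        binary_collapse(WORKED_EXAMPLE_CONFUSION, set())
    with pytest.raises(ValueError):
        binary_collapse(WORKED_EXAMPLE_CONFUSION, {0, 1, 2})


def test_worked_example_metrics_at_printed_precision():
    rep = binary_metrics(binary_collapse(WORKED_EXAMPLE_CONFUSION, {1, 2}))
    assert round(100 * rep.sensitivity, 1) == 97.5
    assert round(100 * rep.specificity, 1) == 98.7
    assert round(100 * rep.precision, 1) == 98.2
    assert round(rep.youden, 3) == 0.962
    # the matrix yields F1 ~ 0.9783; asserted to 2 d.p. only (the companion
    # printed summary rounds it to 0.979)
    assert round(rep.f1, 2) == 0.98
    assert abs(rep.youden - (rep.sensitivity + rep.specificity - 1.0)) < 1e-15


def test_all_correct_binary_matrix_scores_one_everywhere():
    rep = binary_metrics(np.array([[7, 0], [0, 9]]))
    for v in (rep.sensitivity, rep.specificity, rep.precision, rep.f1,
              rep.accuracy):
        assert v == 1.0
    assert rep.youden == 1.0


def test_zero_denominator_reports_nan_not_zero():
    rep = binary_metrics(np.array([[0, 0], [3, 7]]))
    assert np.isnan(rep.sensitivity)


def test_auc_perfect_separation_is_one():
    assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0


def test_auc_toy_three_of_four_pairs():
    assert roc_auc([0.9, 0.3, 0.8, 0.1], [1, 1, 0, 0]) == 0.75


def test_auc_ties_count_half():
    assert roc_auc([0.5, 0.5], [1, 0]) == 0.5


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


def test_auc_near_half_for_uninformative_scores():
    rng = np.random.default_rng(0)
    s = rng.normal(size=2000)
    y = rng.integers(0, 2, 2000)
    assert abs(roc_auc(s, y) - 0.5) < 0.05


@settings(derandomize=True, max_examples=40)
@given(st.integers(0, 10_000))
def test_pairwise_auc_equals_trapezoidal_auc(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 60))
    scores = rng.choice([0.1, 0.25, 0.5, 0.75, 0.9], size=n)  # forces ties
    labels = rng.integers(0, 2, n)
    if labels.min() == labels.max():
        return
    fpr, tpr = roc_curve(scores, labels)
    assert abs(np.trapezoid(tpr, fpr) - roc_auc(scores, labels)) < 1e-10


def test_youden_threshold_on_separable_toy():
    t, rep = youden_threshold([0.1, 0.2, 0.7, 0.9], [0, 0, 1, 1])
    assert t == 0.7
    assert rep.youden == 1.0


def test_youden_threshold_matches_exhaustive_scan():
    rng = np.random.default_rng(1)
    scores = rng.uniform(size=200)
    labels = (scores + rng.normal(scale=0.3, size=200)) > 0.5
    t, rep = youden_threshold(scores, labels)
    best = -np.inf
    for cand in np.unique(scores):
        pred = scores >= cand
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        best = max(best, sens + spec - 1)
    assert np.isclose(rep.youden, best, atol=1e-12)


def test_youden_threshold_shift_invariance():
    scores = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2])
    labels = np.array([0, 1, 0, 1, 1, 0])
    t1, r1 = youden_threshold(scores, labels)
    t2, r2 = youden_threshold(scores + 5.0, labels)
    assert np.isclose(t2 - t1, 5.0)
    assert np.isclose(r1.youden, r2.youden)


def test_every_report_satisfies_youden_identity():
    rng = np.random.default_rng(2)
    for _ in range(5):
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, 50)
        if labels.min() == labels.max():
            continue
        rep = evaluate_scores(scores, labels, threshold=0.5)
        assert abs(rep.youden - (rep.sensitivity + rep.specificity - 1)) < 1e-12


def test_perturbation_report_identity_scores_zero_delta():
    rng = np.random.default_rng(3)
    images = rng.uniform(size=(60, 3, 16, 16)).astype(np.float32)
    labels = rng.integers(0, 3, 60)

    def score_fn(imgs):
        # depends only on labels through a fixed pseudo-random hash of index:
        # perturbation-invariant, so all deltas must be zero
        return np.linspace(0, 1, len(imgs)) + (labels != 0)

    df = perturbation_report(score_fn, images, labels, seed=0)
    assert set(df["condition"]) == {"clean", "brightness", "contrast",
                                    "random_transform"}
    assert np.allclose(df["delta_sensitivity_pp"], 0.0)
    assert np.allclose(df["delta_specificity_pp"], 0.0)
    clean = df[df["condition"] == "clean"].iloc[0]
    assert clean["delta_sensitivity_pp"] == 0.0


def test_auc_matches_scikit_learn_reference():
    from sklearn.metrics import roc_auc_score
    rng = np.random.default_rng(17)
    for _ in range(5):
        scores = rng.normal(size=300)
        labels = rng.integers(0, 2, 300)
        if labels.min() == labels.max():
            continue
        assert abs(roc_auc(scores, labels)
                   - roc_auc_score(labels, scores)) < 1e-12
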