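"""Heads and the composite objective: softmax contracts, Huber properties,
loss identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dudem.nn import Tensor
from dudem.heads import (ClassificationHead, BoxHead, cross_entropy_loss,
                         smooth_l1, bbox_regression_loss, total_loss,
                         inverse_frequency_weights)

RNG = np.random.default_rng(5)


def test_classifier_probabilities_sum_to_one():
    head = ClassificationHead(8, 3, depth=2, seed=0)
    fused = Tensor(RNG.normal(size=(4, 8, 2, 2)).astype(np.float32))
    probs = head(fused).data
    assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-6
    assert (probs >= 0).all()


def test_softmax_closed_forms():
    t = Tensor(np.array([[0.0, np.log(2.0)]]))
    p = t.softmax(axis=-1).data
    assert np.allclose(p, [[1 / 3, 2 / 3]], atol=1e-12)
    # shift invariance
    p2 = (t + 7.3).softmax(axis=-1).data
    assert np.allclose(p, p2, atol=1e-12)
    # equal logits -> uniform
    u = Tensor(np.zeros((1, 5))).softmax(axis=-1).data
    assert np.allclose(u, 0.2)


def test_classifier_rejects_bad_config():
    with pytest.raises(ValueError):
        ClassificationHead(8, 1)
    with pytest.raises(ValueError):
        ClassificationHead(8, 3, depth=3)


def test_box_head_zero_preactivation_centers_box():
    head = BoxHead(8, seed=0)
    head.fc.weight.data[:] = 0.0
    head.fc.bias.data[:] = 0.0
    fused = Tensor(RNG.normal(size=(2, 8, 2, 2)).astype(np.float32))
    assert np.allclose(head(fused).data, 0.5)


def test_box_head_outputs_in_unit_interval():
    head = BoxHead(8, seed=1)
    fused = Tensor((RNG.normal(size=(8, 8, 2, 2)) * 10).astype(np.float32))
    out = head(fused).data
    assert (out >= 0).all() and (out <= 1).all()
    assert np.array_equal(out, head(fused).data)


def test_cross_entropy_perfect_prediction_is_zero():
    probs = Tensor(np.eye(3)[[0, 1, 2]])
    assert float(cross_entropy_loss([0, 1, 2], probs).data) < 1e-10


def test_cross_entropy_uniform_prediction_is_log_k():
    K = 4
    probs = Tensor(np.full((6, K), 1.0 / K))
    loss = float(cross_entropy_loss(np.zeros(6, dtype=int), probs).data)
    assert np.isclose(loss, np.log(K), atol=1e-10)


def test_cross_entropy_class_weights_scale_contributions():
    probs = Tensor(np.array([[0.5, 0.5], [0.5, 0.5]]))
    base = float(cross_entropy_loss([0, 1], probs).data)
    weighted = float(cross_entropy_loss([0, 1], probs,
                                        class_weights=[1.0, 2.0]).data)
    # sample 1's contribution doubles: (l + 2l)/2 = 1.5 l
    assert np.isclose(weighted, 1.5 * base, atol=1e-10)


def test_cross_entropy_clamps_zero_probability():
    probs = Tensor(np.array([[1.0, 0.0]]))
    loss = cross_entropy_loss([1], probs, eps=1e-12)
    assert np.isfinite(float(loss.data))


@pytest.mark.parametrize("x,expected", [
    (0.0, 0.0), (0.5, 0.125), (1.0, 0.5), (-1.0, 0.5), (-2.0, 1.5), (3.0, 2.5),
])
def test_smooth_l1_values(x, expected):
    assert np.isclose(smooth_l1(np.array(x)), expected, atol=1e-12)


def test_smooth_l1_first_derivative_continuous_at_one():
    eps = 1e-6
    for x0 in (1.0, -1.0):
        left = (smooth_l1(np.array(x0)) - smooth_l1(np.array(x0 - eps))) / eps
        right = (smooth_l1(np.array(x0 + eps)) - smooth_l1(np.array(x0))) / eps
        assert abs(left - right) < 1e-4
        assert abs(abs(left) - 1.0) < 1e-4


@settings(derandomize=True, max_examples=60)
@given(st.floats(-50, 50))
def test_smooth_l1_even_and_bounded_by_quadratic(x):
    arr = np.array(x)
    assert np.isclose(smooth_l1(arr), smooth_l1(-arr), atol=1e-12)
    assert smooth_l1(arr) <= 0.5 * x * x + 1e-12


def test_total_loss_identity_and_lambda():
    lb = total_loss(0.3, 0.2, lam=1.0)
    assert np.isclose(float(lb.total.data), 0.5, atol=1e-12)
    lb0 = total_loss(0.3, 0.2, lam=0.0)
    assert np.isclose(float(lb0.total.data), 0.3, atol=1e-15)
    # exact identity
    for lam in (0.0, 0.5, 2.0):
        lb = total_loss(0.7, 0.4, lam=lam)
        assert float(lb.total.data) == float(lb.classification.data) + lam * float(lb.regression.data)


def test_total_loss_monotone_in_lambda_when_regression_positive():
    totals = [float(total_loss(0.3, 0.2, lam=l).total.data) for l in (0.0, 0.5, 1.0, 2.0)]
    assert all(b >= a for a, b in zip(totals, totals[1:]))


def test_regression_loss_masked_out_for_all_normal_batch():
    pred = Tensor(RNG.uniform(size=(4, 4)))
    true = RNG.uniform(size=(4, 4))
    loss = bbox_regression_loss(pred, true, np.zeros(4, dtype=bool))
    assert float(loss.data) == 0.0


def test_regression_loss_matches_manual_masked_mean():
    pred = Tensor(np.array([[0.5, 0.5, 0.5, 0.5], [0.2, 0.2, 0.2, 0.2]]))
    true = np.array([[0.0, 1.0, 0.5, 0.5], [0.9, 0.9, 0.9, 0.9]])
    mask = np.array([True, False])
    got = float(bbox_regression_loss(pred, true, mask).data)
    manual = np.mean([0.5 * 0.25, 0.5 * 0.25, 0.0, 0.0])
    assert np.isclose(got, manual, atol=1e-12)


def test_inverse_frequency_weights_favor_minority():
    w = inverse_frequency_weights(np.array([0] * 90 + [1] * 10), 2)
    assert w[1] > w[0] > 0
    assert np.isclose(w.mean(), 1.0)
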