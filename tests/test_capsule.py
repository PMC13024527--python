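"""Capsule branch: squash, votes, routing-by-agreement and re-spatialization.

Routing is validated against a naive triple-loop oracle that implements the
update rules literally, independently of the vectorized path.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dudem.nn import Tensor
from dudem.capsule import (squash, PrimaryCapsules, predict_votes,
                           dynamic_routing, capsules_to_feature_map,
                           CapsuleBranch)

RNG = np.random.default_rng(7)


# -- independent oracle -------------------------------------------------------

def routing_oracle(votes: np.ndarray, r: int):
    """Literal per-pair implementation of routing-by-agreement."""
    N, K, d = votes.shape
    b = np.zeros((N, K))
    for it in range(r):
        c = np.exp(b - b.max(axis=1, keepdims=True))
        c = c / c.sum(axis=1, keepdims=True)
        v = np.zeros((K, d))
        for j in range(K):
            s = np.zeros(d)
            for i in range(N):
                s += c[i, j] * votes[i, j]
            n2 = (s ** 2).sum()
            v[j] = (n2 / (1 + n2)) * s / (np.sqrt(n2) + 1e-8)
        if it < r - 1:
            for i in range(N):
                for j in range(K):
                    b[i, j] += votes[i, j] @ v[j]
    return v, b, c


# -- squash -------------------------------------------------------------------

def test_squash_zero_vector_is_zero():
    out = squash(np.zeros(8))
    assert np.allclose(out, 0.0)


def test_squash_unit_vector_has_norm_half():
    z = np.zeros(4); z[1] = 1.0
    out = squash(z)
    assert np.isclose(np.linalg.norm(out), 0.5, atol=1e-6)
    assert np.allclose(out / np.linalg.norm(out), z)


def test_squash_norm_three_gives_nine_tenths():
    z = np.full(9, 1.0)  # norm 3
    out = squash(z)
    assert np.isclose(np.linalg.norm(out), 0.9, atol=1e-6)


def test_squash_rejects_non_finite():
    with pytest.raises(ValueError):
        squash(np.array([1.0, np.nan]))


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(-5, 5), min_size=3, max_size=3),
       st.floats(0.01, 3.0))
def test_squash_norm_monotone_and_bounded(direction, scale2):
    z1 = np.asarray(direction)
    if np.linalg.norm(z1) < 1e-3:
        return
    z2 = z1 * (1.0 + scale2)
    n1 = np.linalg.norm(squash(z1))
    n2 = np.linalg.norm(squash(z2))
    assert n1 < n2 < 1.0


# -- primary capsules ---------------------------------------------------------

def test_primary_capsule_count_and_dim():
    pc = PrimaryCapsules(in_channels=32, caps_per_cell=4, d=8,
                         rng=np.random.default_rng(0))
    fm = Tensor(RNG.normal(size=(2, 32, 2, 2)).astype(np.float32))
    u = pc(fm)
    assert u.shape == (2, 16, 8)     # 2x2 cells x 4 caps, dim 8


def test_primary_capsules_zero_map_gives_zero_capsules():
    pc = PrimaryCapsules(16, 4, 8, rng=np.random.default_rng(0))
    u = pc(Tensor(np.zeros((1, 16, 3, 3), dtype=np.float32)))
    assert np.allclose(u.data, 0.0)  # bias-free conv + squash(0) = 0


def test_primary_capsule_norms_below_one():
    pc = PrimaryCapsules(16, 4, 8, rng=np.random.default_rng(1))
    worst = 0.0
    for k in range(20):
        fm = Tensor(np.random.default_rng(k).normal(
            size=(4, 16, 3, 3), scale=5.0).astype(np.float32))
        u = pc(fm)
        worst = max(worst, float(np.linalg.norm(u.data, axis=-1).max()))
    assert worst < 1.0


# -- votes --------------------------------------------------------------------

def test_votes_identity_transform_returns_capsules():
    u = RNG.normal(size=(2, 5, 4))
    W = np.broadcast_to(np.eye(4), (5, 3, 4, 4)).copy()
    votes = predict_votes(u, W)
    for j in range(3):
        assert np.allclose(votes.data[:, :, j], u, atol=1e-12)


def test_votes_zero_weights_give_zero_votes():
    u = RNG.normal(size=(1, 4, 4))
    votes = predict_votes(u, np.zeros((4, 2, 6, 4)))
    assert np.allclose(votes.data, 0.0)


def test_votes_match_per_pair_loop_oracle():
    B, N, K, d, dp = 2, 6, 3, 4, 5
    u = RNG.normal(size=(B, N, d))
    W = RNG.normal(size=(N, K, dp, d))
    votes = predict_votes(u, W).data
    for b in range(B):
        for i in range(N):
            for j in range(K):
                assert np.allclose(votes[b, i, j], W[i, j] @ u[b, i], atol=1e-6)


def test_votes_shared_weights_tile_over_positions():
    T, P, K, d, dp = 2, 3, 2, 4, 4
    u = RNG.normal(size=(1, P * T, d))
    W = RNG.normal(size=(T, K, dp, d))
    votes = predict_votes(u, W, caps_per_cell=T).data
    for p in range(P):
        for t in range(T):
            i = p * T + t
            for j in range(K):
                assert np.allclose(votes[0, i, j], W[t, j] @ u[0, i], atol=1e-6)


def test_votes_dimension_mismatch_raises():
    with pytest.raises(ValueError):
        predict_votes(RNG.normal(size=(1, 4, 5)), RNG.normal(size=(4, 2, 6, 4)))


# -- routing ------------------------------------------------------------------

def test_routing_single_pair_is_squash_of_vote():
    votes = RNG.normal(size=(1, 1, 1, 6))
    v, state = dynamic_routing(votes, r=3)
    assert np.allclose(state["couplings"].data, 1.0, atol=1e-12)
    assert np.allclose(v.data[0, 0], squash(votes[0, 0, 0]), atol=1e-7)


def test_routing_one_iteration_uses_uniform_couplings():
    votes = RNG.normal(size=(1, 4, 3, 5))
    v, state = dynamic_routing(votes, r=1)
    assert np.allclose(state["couplings"].data, 1.0 / 3.0, atol=1e-12)
    expected = squash((votes[0] / 3.0).sum(axis=0))
    assert np.allclose(v.data[0], expected, atol=1e-7)


def test_routing_requires_at_least_one_iteration():
    with pytest.raises(ValueError):
        dynamic_routing(RNG.normal(size=(1, 2, 2, 3)), r=0)


def test_routing_aligned_votes_win_couplings_monotonically():
    # capsules 0 and 1 vote identically for class 0; capsule 2 votes
    # orthogonally — agreement should pull couplings of 0,1 above 1/2 for
    # class 0 and grow monotonically with iterations
    aligned = np.array([1.0, 0.0, 0.0, 0.0])
    ortho = np.array([0.0, 1.0, 0.0, 0.0])
    votes = np.zeros((1, 3, 2, 4))
    votes[0, 0, 0] = aligned * 2
    votes[0, 1, 0] = aligned * 2
    votes[0, 2, 0] = ortho * 2
    votes[0, :, 1] = RNG.normal(size=(3, 4)) * 0.1
    prev = 0.5
    for r in (1, 2, 3, 4):
        _, state = dynamic_routing(votes, r=r)
        c = state["couplings"].data[0]
        assert abs(c.sum(axis=1) - 1.0).max() < 1e-6
        cur = c[0, 0]
        assert cur >= prev - 1e-12
        prev = cur
    assert prev > 0.5


@pytest.mark.parametrize("trial", range(10))
def test_vectorized_routing_matches_triple_loop_oracle(trial):
    rng = np.random.default_rng(100 + trial)
    N = int(rng.integers(1, 21))
    K = int(rng.integers(1, 6))
    r = int(rng.integers(1, 5))
    votes = rng.normal(size=(1, N, K, 8))
    v, state = dynamic_routing(votes, r=r)
    v_o, b_o, c_o = routing_oracle(votes[0], r)
    assert np.abs(v.data[0] - v_o).max() < 1e-5
    assert np.abs(state["couplings"].data[0] - c_o).max() < 1e-5
    assert np.abs(state["logits"].data[0] - b_o).max() < 1e-5


@settings(derandomize=True, max_examples=25)
@given(st.integers(0, 10_000))
def test_coupling_rows_sum_to_one_every_iteration(seed):
    rng = np.random.default_rng(seed)
    votes = rng.normal(size=(1, int(rng.integers(2, 10)), int(rng.integers(2, 5)), 4))
    for r in (1, 2, 3):
        v, state = dynamic_routing(votes, r=r)
        c = state["couplings"].data
        assert np.abs(c.sum(axis=-1) - 1.0).max() < 1e-6
        assert (c > 0).all()
        assert np.linalg.norm(v.data, axis=-1).max() < 1.0


# -- re-spatialization --------------------------------------------------------

def test_feature_map_channel_arithmetic():
    caps = RNG.normal(size=(2, 3, 16))
    fm = capsules_to_feature_map(caps, (7, 7))
    assert fm.shape == (2, 48, 7, 7)


def test_zero_capsules_give_zero_map():
    fm = capsules_to_feature_map(np.zeros((1, 2, 4)), (3, 3))
    assert np.allclose(fm.data, 0.0)


def test_broadcast_mode_tiles_same_vector_everywhere():
    caps = RNG.normal(size=(1, 2, 4))
    fm = capsules_to_feature_map(caps, (3, 5)).data
    flat = caps.reshape(8)
    for y in range(3):
        for x in range(5):
            assert np.allclose(fm[0, :, y, x], flat)


def test_branch_output_matches_conv_branch_spatial_dims():
    branch = CapsuleBranch(in_channels=16, k_classes=3, spatial_hw=(2, 2),
                           caps_per_cell=4, d_primary=4, d_category=8, seed=0)
    fm = Tensor(RNG.normal(size=(2, 16, 2, 2)).astype(np.float32))
    out = branch(fm)
    assert out.shape == (2, 24, 2, 2)
    assert branch.out_channels == 24
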