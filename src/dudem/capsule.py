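"""Capsule branch: primary capsules, votes, routing-by-agreement, and
re-spatialization of category capsules into a pose-aware feature map.

A capsule is a vector-valued unit: its norm encodes the probability that an
entity is present, its direction the entity's pose.  Primary capsules are
formed from a feature map by a 1x1 capsule-forming convolution that groups
channels into ``caps_per_cell`` capsule types of dimension ``d`` at every
spatial cell, each passed through the squash nonlinearity

    squash(z) = (|z|^2 / (1 + |z|^2)) * z / (|z| + eps),

which compresses norms into [0, 1) while preserving direction.  Each primary
capsule i votes for every category capsule j through an affine map
``u_hat[j|i] = W_ij @ u_i``; votes are combined by iterative
routing-by-agreement:

    c_ij = softmax_j(b_ij)
    s_j  = sum_i c_ij u_hat[j|i]
    v_j  = squash(s_j)
    b_ij <- b_ij + u_hat[j|i] . v_j

with logits ``b`` initialized to zero, so the first pass uses uniform
couplings 1/K.  Transform weights are shared across spatial positions within
a capsule type by default (a per-pair option exists for small exact tests).

Unstated hyperparameters use the established conventions: routing iterations
r = 3, primary capsule dimension d = 8, category capsule dimension d' = 16.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, Module, Parameter, Conv2d

__all__ = [
    "squash", "PrimaryCapsules", "predict_votes", "dynamic_routing",
    "capsules_to_feature_map", "CapsuleBranch",
]


def squash(z, axis: int = -1, eps: float = 1e-8):
    """Squash nonlinearity; accepts a Tensor or ndarray (ndarray in, ndarray out)."""
    was_array = not isinstance(z, Tensor)
    t = Tensor(z) if was_array else z
    if not np.all(np.isfinite(t.data)):
        raise ValueError("squash received non-finite input")
    sq = (t * t).sum(axis=axis, keepdims=True)
    norm = sq.sqrt()
    scale = norm / (1.0 + sq) / (norm + eps) * norm
    out = t * scale
    return out.data if was_array else out


class PrimaryCapsules(Module):
    """Capsule-forming 1x1 convolution over a feature map.

    Produces N = H*W*caps_per_cell squashed capsules of dimension ``d``,
    retaining capsule -> cell provenance in the output layout
    (B, H, W, caps_per_cell, d) flattened to (B, N, d).
    """

    def __init__(self, in_channels: int, caps_per_cell: int, d: int, rng=None):
        super().__init__()
        self.caps_per_cell = caps_per_cell
        self.d = d
        out_ch = caps_per_cell * d
        if out_ch < 1:
            raise ValueError("caps_per_cell * d must be positive")
        self.conv = Conv2d(in_channels, out_ch, 1, rng=rng)

    def forward(self, fm: Tensor):
        B, C, H, W = fm.shape
        z = self.conv(fm)                                   # B, T*d, H, W
        z = z.reshape(B, self.caps_per_cell, self.d, H, W)
        z = z.transpose(0, 3, 4, 1, 2)                      # B, H, W, T, d
        u = squash(z, axis=-1)
        self.spatial = (H, W)
        return u.reshape(B, H * W * self.caps_per_cell, self.d)


class CapsuleTransform(Module):
    """Affine vote prediction u_hat[j|i] = W_ij @ u_i.

    ``shared=True`` (default) shares W across spatial positions within each of
    the ``caps_per_cell`` capsule types: W has shape (T, K, d_out, d_in) and
    capsule i of type t uses W[t].  ``shared=False`` keeps a full per-pair
    (N, K, d_out, d_in) weight, used by small exact oracles.
    """

    def __init__(self, n_caps: int, caps_per_cell: int, k_classes: int,
                 d_in: int, d_out: int, shared: bool = True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.shared = shared
        self.caps_per_cell = caps_per_cell
        self.k_classes = k_classes
        self.d_in, self.d_out = d_in, d_out
        lead = caps_per_cell if shared else n_caps
        w = rng.normal(0.0, 0.1, size=(lead, k_classes, d_out, d_in))
        self.weight = Parameter(w.astype(np.float32))

    def forward(self, u: Tensor) -> Tensor:
        return predict_votes(u, self.weight, caps_per_cell=self.caps_per_cell
                             if self.shared else None)


def predict_votes(u, W, caps_per_cell=None):
    """Compute the vote tensor (B, N, K, d_out).

    ``u``: capsules (B, N, d_in).  ``W``: per-pair weights (N, K, d_out, d_in),
    or type-shared weights (T, K, d_out, d_in) with ``caps_per_cell=T`` when N
    is laid out as (positions x T).
    """
    u = u if isinstance(u, Tensor) else Tensor(u)
    W = W if isinstance(W, Tensor) else Tensor(W)
    B, N, d_in = u.shape
    if W.shape[-1] != d_in:
        raise ValueError(f"W last dim {W.shape[-1]} != capsule dim {d_in}")
    K, d_out = W.shape[1], W.shape[2]
    if caps_per_cell is None:
        if W.shape[0] != N:
            raise ValueError(f"per-pair W has N={W.shape[0]}, capsules N={N}")
        Wb = W.reshape(1, N, K, d_out, d_in)
    else:
        T = caps_per_cell
        if N % T:
            raise ValueError(f"N={N} not divisible by caps_per_cell={T}")
        P = N // T
        Wb = (W.reshape(1, 1, T, K, d_out, d_in)
               .expand((1, P, T, K, d_out, d_in))
               .reshape(1, N, K, d_out, d_in))
    ub = u.reshape(B, N, 1, d_in, 1)
    votes = Wb @ ub                                         # B, N, K, d_out, 1
    return votes.reshape(B, N, K, d_out)


def dynamic_routing(votes, r: int = 3, return_state: bool = True):
    """Routing-by-agreement over the capsule axis.

    ``votes``: (..., N, K, d') — leading axes are batch-like (routing runs
    independently per leading index).  Returns category capsules
    (..., K, d') and, optionally, the final routing state
    ``(logits b, couplings c, iteration)`` with b, c of shape (..., N, K).
    """
    v_t = votes if isinstance(votes, Tensor) else Tensor(votes)
    if r < 1:
        raise ValueError("routing iteration count r must be >= 1")
    lead = v_t.shape[:-3]
    N, K, d_out = v_t.shape[-3:]
    b = Tensor(np.zeros(lead + (N, K), dtype=v_t.dtype))
    v = None
    c = None
    for it in range(r):
        c = b.softmax(axis=-1)                              # couplings over j
        s = (c.reshape(c.shape + (1,)) * v_t).sum(axis=-3)  # ..., K, d'
        v = squash(s, axis=-1)
        if it < r - 1:
            agreement = (v_t * v.reshape(lead + (1, K, d_out))).sum(axis=-1)
            b = b + agreement
    if not return_state:
        return v
    state = {"logits": b, "couplings": c, "iteration": r}
    return v, state


def capsules_to_feature_map(caps, target_hw, mode: str = "broadcast"):
    """Re-spatialize category capsules into a (B, K*d', H, W) feature map.

    ``broadcast`` tiles the flattened K*d' category vector to every cell
    (caps shaped (B, K, d')); ``per_cell`` expects per-cell capsules shaped
    (B, H, W, K, d') and lays them out channelwise.
    """
    t = caps if isinstance(caps, Tensor) else Tensor(caps)
    H, W = target_hw
    if mode == "broadcast":
        B, K, d = t.shape
        flat = t.reshape(B, K * d, 1, 1)
        return flat.expand((B, K * d, H, W))
    if mode == "per_cell":
        B, Hc, Wc, K, d = t.shape
        if (Hc, Wc) != (H, W):
            raise ValueError(f"per-cell capsules at {Hc}x{Wc}, target {H}x{W}")
        return t.reshape(B, H, W, K * d).transpose(0, 3, 1, 2)
    raise ValueError(f"unknown re-spatialization mode {mode!r}")


class CapsuleBranch(Module):
    """Full capsule pathway: primary capsules -> votes -> routing -> map."""

    def __init__(self, in_channels: int, k_classes: int, spatial_hw,
                 caps_per_cell: int = 8, d_primary: int = 8,
                 d_category: int = 16, routing_iters: int = 3,
                 respatialize: str = "broadcast", seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.k_classes = k_classes
        self.d_category = d_category
        self.routing_iters = routing_iters
        self.respatialize = respatialize
        self.spatial_hw = tuple(spatial_hw)
        self.primary = PrimaryCapsules(in_channels, caps_per_cell, d_primary, rng=rng)
        n_caps = spatial_hw[0] * spatial_hw[1] * caps_per_cell
        self.transform = CapsuleTransform(n_caps, caps_per_cell, k_classes,
                                          d_primary, d_category, rng=rng)

    @property
    def out_channels(self) -> int:
        return self.k_classes * self.d_category

    def forward(self, fm: Tensor) -> Tensor:
        H, W = fm.shape[2], fm.shape[3]
        u = self.primary(fm)                                # B, N, d
        votes = self.transform(u)                           # B, N, K, d'
        if self.respatialize == "per_cell":
            B, N, K, d = votes.shape
            T = self.primary.caps_per_cell
            per_cell = votes.reshape(B, H, W, T, K, d)
            v = dynamic_routing(per_cell, r=self.routing_iters, return_state=False)
            return capsules_to_feature_map(v, (H, W), mode="per_cell")
        v = dynamic_routing(votes, r=self.routing_iters, return_state=False)
        self.category_capsules = v.detach()
        return capsules_to_feature_map(v, (H, W), mode="broadcast")
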