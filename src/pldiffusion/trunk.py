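"""Residual feature-update trunk: gated attention with pair bias, the outer
product update, and triangle multiplicative updates.

Each block applies, residually and in this order: single-representation
attention (SRA) -> outer product update (OPU) -> triangle update (outgoing)
-> triangle update (incoming).  Weights are per-block.  The trunk never sees
3D coordinates; geometry enters only through the distance features already
baked into the pair representation.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, einsum
from .config import RunConfig
from .featurize import PairRepresentation, SingleRepresentation
from .nn import LayerNorm, Linear, Module

__all__ = ["SRABlock", "OuterProductUpdate", "TriangleUpdate", "Trunk"]


class SRABlock(Module):
    """Gated multi-head attention over tokens with an additive pair bias.

    Line-by-line: LayerNorm(m); no-bias linear q,k,v per head of width C;
    pair bias b from a no-bias linear on LayerNorm(z); gate
    g = sigmoid(Linear(m)); a = softmax_j(q k^T / sqrt(C) + b);
    o = g * sum_j a v; output linear on the head concatenation, added to the
    input residually.
    """

    def __init__(self, cfg: RunConfig, rng: np.random.Generator):
        c_m, c_z = cfg.c_m, cfg.c_z
        self.heads = cfg.sra_heads
        self.head_dim = cfg.sra_head_dim
        width = self.heads * self.head_dim
        self.m_norm = LayerNorm(c_m)
        self.z_norm = LayerNorm(c_z)
        self.q_proj = Linear(c_m, width, rng, bias=False)
        self.k_proj = Linear(c_m, width, rng, bias=False)
        self.v_proj = Linear(c_m, width, rng, bias=False)
        self.bias_proj = Linear(c_z, self.heads, rng, bias=False)
        self.gate_proj = Linear(c_m, width, rng)
        self.out_proj = Linear(width, c_m, rng)

    def attention(self, single: Tensor, pair: Tensor) -> Tensor:
        """Attention weights a_sijh (softmax over j)."""
        b, r, _ = single.shape
        h, c = self.heads, self.head_dim
        m = self.m_norm(single)
        q = self.q_proj(m).reshape(b, r, h, c)
        k = self.k_proj(m).reshape(b, r, h, c)
        bias = self.bias_proj(self.z_norm(pair))  # (b, r, r, h)
        logits = einsum("bihc,bjhc->bijh", q, k) * (1.0 / np.sqrt(c)) + bias
        return logits.softmax(axis=2)

    def __call__(self, single: Tensor, pair: Tensor) -> Tensor:
        b, r, _ = single.shape
        h, c = self.heads, self.head_dim
        m = self.m_norm(single)
        v = self.v_proj(m).reshape(b, r, h, c)
        g = self.gate_proj(m).reshape(b, r, h, c).sigmoid()
        a = self.attention(single, pair)
        o = g * einsum("bijh,bjhc->bihc", a, v)
        update = self.out_proj(o.reshape(b, r, h * c))
        return single + update


class OuterProductUpdate(Module):
    """Lift per-token features to a pairwise update via a Kronecker product.

    a_i, b_j are C-dim linear projections of LayerNorm(m); the flattened
    outer product a_i (x) b_j is mapped linearly to c_z.  No averaging over
    any axis.
    """

    def __init__(self, cfg: RunConfig, rng: np.random.Generator):
        self.c = cfg.opu_hidden
        self.norm = LayerNorm(cfg.c_m)
        self.a_proj = Linear(cfg.c_m, self.c, rng)
        self.b_proj = Linear(cfg.c_m, self.c, rng)
        self.out_proj = Linear(self.c * self.c, cfg.c_z, rng)

    def __call__(self, single: Tensor) -> Tensor:
        b, r, _ = single.shape
        m = self.norm(single)
        a = self.a_proj(m)
        bb = self.b_proj(m)
        outer = einsum("bic,bjd->bijcd", a, bb).reshape(b, r, r, self.c * self.c)
        return self.out_proj(outer)


class TriangleUpdate(Module):
    """Multiplicative triangle update mixing edges through a shared node k.

    outgoing: u_ij = sum_k a_ik * b_jk;  incoming: u_ij = sum_k a_ki * b_kj,
    with a, b gated linear projections of LayerNorm(z) and a final gated
    projection of LayerNorm(u), applied residually by the trunk.
    """

    def __init__(self, cfg: RunConfig, rng: np.random.Generator, direction: str):
        if direction not in ("outgoing", "incoming"):
            raise ValueError(f"unknown triangle direction: {direction!r}")
        self.direction = direction
        c_z, hidden = cfg.c_z, cfg.tri_hidden
        self.in_norm = LayerNorm(c_z)
        self.a_proj = Linear(c_z, hidden, rng)
        self.a_gate = Linear(c_z, hidden, rng)
        self.b_proj = Linear(c_z, hidden, rng)
        self.b_gate = Linear(c_z, hidden, rng)
        self.u_norm = LayerNorm(hidden)
        self.out_proj = Linear(hidden, c_z, rng)
        self.out_gate = Linear(c_z, c_z, rng)

    def __call__(self, pair: Tensor) -> Tensor:
        z = self.in_norm(pair)
        a = self.a_gate(z).sigmoid() * self.a_proj(z)
        b = self.b_gate(z).sigmoid() * self.b_proj(z)
        if self.direction == "outgoing":
            u = einsum("bikc,bjkc->bijc", a, b)
        else:
            u = einsum("bkic,bkjc->bijc", a, b)
        return self.out_gate(z).sigmoid() * self.out_proj(self.u_norm(u))


class TrunkBlock(Module):
    def __init__(self, cfg: RunConfig, rng: np.random.Generator):
        self.sra = SRABlock(cfg, rng)
        self.opu = OuterProductUpdate(cfg, rng)
        self.tri_out = TriangleUpdate(cfg, rng, "outgoing")
        self.tri_in = TriangleUpdate(cfg, rng, "incoming")

    def __call__(self, single: Tensor, pair: Tensor) -> tuple[Tensor, Tensor]:
        single = self.sra(single, pair)  # residual inside
        pair = pair + self.opu(single)
        pair = pair + self.tri_out(pair)
        pair = pair + self.tri_in(pair)
        return single, pair


class Trunk(Module):
    """``n_blocks`` repetitions of [SRA -> OPU -> tri-out -> tri-in]."""

    def __init__(self, cfg: RunConfig, rng: np.random.Generator):
        self.blocks = [TrunkBlock(cfg, rng) for _ in range(cfg.n_blocks)]

    def __call__(
        self, single: SingleRepresentation, pair: PairRepresentation
    ) -> tuple[SingleRepresentation, PairRepresentation]:
        m, z = single.values, pair.values
        for i, block in enumerate(self.blocks):
            m, z = block(m, z)
            if not (np.isfinite(m.data).all() and np.isfinite(z.data).all()):
                raise FloatingPointError(f"non-finite representation after trunk block {i}")
        out_single = SingleRepresentation(
            values=m, token_kinds=single.token_kinds,
            n_res=single.n_res, n_atoms=single.n_atoms,
        )
        return out_single, PairRepresentation(values=z)
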