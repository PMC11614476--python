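"""Trunk modules checked against independent straight-line transcriptions."""

import numpy as np
import pytest

from pldiffusion._tensor import Tensor
from pldiffusion.config import RunConfig, TINY
from pldiffusion.featurize import PairRepresentation, SingleRepresentation
from pldiffusion.nn import LAYERNORM_EPS
from pldiffusion.trunk import OuterProductUpdate, SRABlock, TriangleUpdate, Trunk

CFG = RunConfig(**TINY, seed=0)


def make_inputs(r, seed=0, c_m=CFG.c_m, c_z=CFG.c_z):
    rng = np.random.default_rng(seed)
    m = rng.standard_normal((1, r, c_m))
    z = rng.standard_normal((1, r, r, c_z))
    return m, z


def _ln(x, gamma, beta):
    mu = x.mean(-1, keepdims=True)
    var = ((x - mu) ** 2).mean(-1, keepdims=True)
    return (x - mu) / np.sqrt(var + LAYERNORM_EPS) * gamma + beta


def sra_oracle(m, z, blk: SRABlock):
    """Loop transcription of the gated pair-biased attention pseudocode."""
    r = m.shape[0]
    h, c = blk.heads, blk.head_dim
    mn = _ln(m, blk.m_norm.gamma.data, blk.m_norm.beta.data)
    zn = _ln(z, blk.z_norm.gamma.data, blk.z_norm.beta.data)
    q = (mn @ blk.q_proj.weight.data).reshape(r, h, c)
    k = (mn @ blk.k_proj.weight.data).reshape(r, h, c)
    v = (mn @ blk.v_proj.weight.data).reshape(r, h, c)
    b = zn @ blk.bias_proj.weight.data  # (r, r, h)
    g = 1 / (1 + np.exp(-(mn @ blk.gate_proj.weight.data + blk.gate_proj.bias.data)))
    g = g.reshape(r, h, c)
    out = np.zeros((r, h, c))
    attn = np.zeros((r, r, h))
    for i in range(r):
        for head in range(h):
            logits = np.array(
                [q[i, head] @ k[j, head] / np.sqrt(c) + b[i, j, head] for j in range(r)]
            )
            a = np.exp(logits - logits.max())
            a /= a.sum()
            attn[i, :, head] = a
            o = sum(a[j] * v[j, head] for j in range(r))
            out[i, head] = g[i, head] * o
    update = out.reshape(r, h * c) @ blk.out_proj.weight.data + blk.out_proj.bias.data
    return m + update, attn


def opu_oracle(m, opu: OuterProductUpdate):
    """Double loop over (i, j) of the cross outer product."""
    r = m.shape[0]
    mn = _ln(m, opu.norm.gamma.data, opu.norm.beta.data)
    a = mn @ opu.a_proj.weight.data + opu.a_proj.bias.data
    b = mn @ opu.b_proj.weight.data + opu.b_proj.bias.data
    out = np.zeros((r, r, opu.out_proj.weight.data.shape[1]))
    for i in range(r):
        for j in range(r):
            flat = np.outer(a[i], b[j]).reshape(-1)
            out[i, j] = flat @ opu.out_proj.weight.data + opu.out_proj.bias.data
    return out


@pytest.mark.parametrize("r", [3, 4, 6])
def test_sra_matches_straight_line_oracle(r):
    rng = np.random.default_rng(r)
    blk = SRABlock(CFG, rng)
    m, z = make_inputs(r, seed=10 + r)
    got = blk(Tensor(m), Tensor(z)).numpy()[0]
    want, _ = sra_oracle(m[0], z[0], blk)
    np.testing.assert_allclose(got, want, atol=1e-6)


def test_attention_rows_sum_to_one():
    blk = SRABlock(CFG, np.random.default_rng(0))
    m, z = make_inputs(5, seed=3)
    a = blk.attention(Tensor(m), Tensor(z)).numpy()[0]
    assert (a >= 0).all()
    np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-6)


def test_uniform_attention_with_crafted_weights():
    blk = SRABlock(CFG, np.random.default_rng(0))
    blk.q_proj.weight.data[:] = 0.0  # q = 0 -> logits from bias only
    blk.bias_proj.weight.data[:] = 0.0  # bias = 0 -> uniform rows
    m, z = make_inputs(4, seed=5)
    a = blk.attention(Tensor(m), Tensor(z)).numpy()[0]
    np.testing.assert_allclose(a, 0.25, atol=1e-12)


def test_closed_gate_passes_input_through():
    blk = SRABlock(CFG, np.random.default_rng(0))
    blk.gate_proj.bias.data[:] = -1e9  # sigmoid -> 0
    blk.out_proj.bias.data[:] = 0.0
    m, z = make_inputs(4, seed=6)
    got = blk(Tensor(m), Tensor(z)).numpy()
    np.testing.assert_allclose(got, m, atol=1e-12)


def test_sra_without_pair_bias_is_gated_multihead_attention():
    """With b = 0 the block reduces to standard gated MHA (reference impl)."""
    blk = SRABlock(CFG, np.random.default_rng(1))
    blk.bias_proj.weight.data[:] = 0.0
    r = 6
    m, z = make_inputs(r, seed=9)

    # independent reference: plain gated multi-head attention
    h, c = blk.heads, blk.head_dim
    mn = _ln(m[0], blk.m_norm.gamma.data, blk.m_norm.beta.data)
    q = (mn @ blk.q_proj.weight.data).reshape(r, h, c).transpose(1, 0, 2)
    k = (mn @ blk.k_proj.weight.data).reshape(r, h, c).transpose(1, 0, 2)
    v = (mn @ blk.v_proj.weight.data).reshape(r, h, c).transpose(1, 0, 2)
    logits = q @ k.transpose(0, 2, 1) / np.sqrt(c)
    e = np.exp(logits - logits.max(-1, keepdims=True))
    attn = e / e.sum(-1, keepdims=True)
    ctx = (attn @ v).transpose(1, 0, 2)
    gate = 1 / (1 + np.exp(-(mn @ blk.gate_proj.weight.data + blk.gate_proj.bias.data)))
    ref = m[0] + (gate.reshape(r, h, c) * ctx).reshape(r, h * c) @ blk.out_proj.weight.data \
        + blk.out_proj.bias.data
    got = blk(Tensor(m), Tensor(z)).numpy()[0]
    np.testing.assert_allclose(got, ref, atol=1e-6)


def test_opu_matches_loop_oracle():
    cfg = RunConfig(**{**TINY, "opu_hidden": 2, "c_m": 5, "c_z": 4})
    opu = OuterProductUpdate(cfg, np.random.default_rng(2))
    m, _ = make_inputs(3, seed=4, c_m=5, c_z=4)
    got = opu(Tensor(m)).numpy()[0]
    np.testing.assert_allclose(got, opu_oracle(m[0], opu), atol=1e-6)


def test_opu_annihilated_projection_leaves_bias():
    opu = OuterProductUpdate(CFG, np.random.default_rng(2))
    opu.a_proj.weight.data[:] = 0.0
    opu.a_proj.bias.data[:] = 0.0
    m, _ = make_inputs(3, seed=4)
    got = opu(Tensor(m)).numpy()[0]
    want = np.broadcast_to(opu.out_proj.bias.data, got.shape)
    np.testing.assert_allclose(got, want, atol=1e-12)


def test_opu_unit_basis_kronecker_position():
    """a = e1, b = e2 puts the single nonzero at flat index of (1, 2)."""
    c = CFG.opu_hidden
    opu = OuterProductUpdate(CFG, np.random.default_rng(2))
    opu.norm.gamma.data[:] = 0.0  # normalized input -> 0, projections = bias
    opu.a_proj.weight.data[:] = 0.0
    opu.b_proj.weight.data[:] = 0.0
    opu.a_proj.bias.data[:] = np.eye(c)[1]
    opu.b_proj.bias.data[:] = np.eye(c)[2]
    opu.out_proj.bias.data[:] = 0.0
    m, _ = make_inputs(2, seed=4)
    got = opu(Tensor(m)).numpy()[0]
    want = np.broadcast_to(opu.out_proj.weight.data[1 * c + 2], got.shape)
    np.testing.assert_allclose(got, want, atol=1e-12)


def test_triangle_zero_input_zero_update():
    tri = TriangleUpdate(CFG, np.random.default_rng(3), "outgoing")
    for lin in (tri.a_proj, tri.a_gate, tri.b_proj, tri.b_gate, tri.out_proj, tri.out_gate):
        lin.bias.data[:] = 0.0
    z = np.zeros((1, 4, 4, CFG.c_z))
    got = tri(Tensor(z)).numpy()
    np.testing.assert_allclose(got, 0.0, atol=1e-12)


@pytest.mark.parametrize("direction", ["outgoing", "incoming"])
def test_triangle_matches_hand_expansion_r2(direction):
    tri = TriangleUpdate(CFG, np.random.default_rng(4), direction)
    rng = np.random.default_rng(7)
    z = rng.standard_normal((1, 2, 2, CFG.c_z))

    zn = _ln(z[0], tri.in_norm.gamma.data, tri.in_norm.beta.data)
    sig = lambda x: 1 / (1 + np.exp(-x))
    lin = lambda l, x: x @ l.weight.data + l.bias.data
    a = sig(lin(tri.a_gate, zn)) * lin(tri.a_proj, zn)
    b = sig(lin(tri.b_gate, zn)) * lin(tri.b_proj, zn)
    u = np.zeros_like(a)
    for i in range(2):
        for j in range(2):
            if direction == "outgoing":
                u[i, j] = a[i, 0] * b[j, 0] + a[i, 1] * b[j, 1]
            else:
                u[i, j] = a[0, i] * b[0, j] + a[1, i] * b[1, j]
    un = _ln(u, tri.u_norm.gamma.data, tri.u_norm.beta.data)
    want = sig(lin(tri.out_gate, zn)) * lin(tri.out_proj, un)
    got = tri(Tensor(z)).numpy()[0]
    np.testing.assert_allclose(got, want, atol=1e-8)


def test_triangle_outgoing_incoming_transpose_identity():
    """Index relabeling: outgoing(z) = incoming(z^T)^T with the a/b
    projections swapped (the edge roles exchange under transposition)."""
    rng = np.random.default_rng(5)
    out_upd = TriangleUpdate(CFG, np.random.default_rng(8), "outgoing")
    in_upd = TriangleUpdate(CFG, np.random.default_rng(9), "incoming")
    # tie weights, swapping the a/b edge projections
    in_upd.in_norm, in_upd.u_norm = out_upd.in_norm, out_upd.u_norm
    in_upd.out_proj, in_upd.out_gate = out_upd.out_proj, out_upd.out_gate
    in_upd.a_proj, in_upd.a_gate = out_upd.b_proj, out_upd.b_gate
    in_upd.b_proj, in_upd.b_gate = out_upd.a_proj, out_upd.a_gate
    z = rng.standard_normal((1, 5, 5, CFG.c_z))
    zt = z.transpose(0, 2, 1, 3)
    a = out_upd(Tensor(z)).numpy()
    b = in_upd(Tensor(zt)).numpy().transpose(0, 2, 1, 3)
    np.testing.assert_allclose(a, b, atol=1e-10)


def test_unknown_direction_rejected():
    with pytest.raises(ValueError, match="direction"):
        TriangleUpdate(CFG, np.random.default_rng(0), "sideways")


def _wrap(m, z):
    r = m.shape[1]
    single = SingleRepresentation(
        values=Tensor(m), token_kinds=np.zeros(r, dtype=np.int64), n_res=r, n_atoms=0
    )
    return single, PairRepresentation(values=Tensor(z))


def test_trunk_zero_blocks_is_identity():
    cfg = RunConfig(**{**TINY, "n_blocks": 0})
    trunk = Trunk(cfg, np.random.default_rng(0))
    m, z = make_inputs(4, seed=1)
    s, p = _wrap(m, z)
    s2, p2 = trunk(s, p)
    np.testing.assert_array_equal(s2.values.numpy(), m)
    np.testing.assert_array_equal(p2.values.numpy(), z)


def test_trunk_deterministic():
    trunk = Trunk(RunConfig(**{**TINY, "n_blocks": 2}), np.random.default_rng(11))
    m, z = make_inputs(5, seed=2)
    outs = []
    for _ in range(2):
        s, p = _wrap(m, z)
        s2, p2 = trunk(s, p)
        outs.append((s2.values.numpy().copy(), p2.values.numpy().copy()))
    np.testing.assert_array_equal(outs[0][0], outs[1][0])
    np.testing.assert_array_equal(outs[0][1], outs[1][1])


def test_trunk_token_permutation_equivariance():
    """Shared per-token weights commute with any token relabeling."""
    trunk = Trunk(RunConfig(**{**TINY, "n_blocks": 2}), np.random.default_rng(12))
    m, z = make_inputs(6, seed=3)
    perm = np.array([3, 1, 5, 0, 4, 2])
    s, p = _wrap(m, z)
    s_perm, p_perm = _wrap(m[:, perm], z[:, perm][:, :, perm])
    base_s, base_p = trunk(s, p)
    got_s, got_p = trunk(s_perm, p_perm)
    np.testing.assert_allclose(got_s.values.numpy(), base_s.values.numpy()[:, perm], atol=1e-10)
    np.testing.assert_allclose(
        got_p.values.numpy(), base_p.values.numpy()[:, perm][:, :, perm], atol=1e-10
    )
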