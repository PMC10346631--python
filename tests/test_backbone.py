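"""Backbone unit tests: tokenisation, windowed attention, block wiring."""

import math

import numpy as np
import pytest

from grainseg import tensor as T
from grainseg.backbone import (
    Backbone,
    PatchEmbed,
    PatchMerging,
    TransformerBlock,
    WindowAttention,
    multi_head_attention,
    scaled_attention,
    sw_msa,
    w_msa,
    window_partition,
)
from grainseg.config import BackboneConfig
from grainseg.tensor import Tensor

RNG = np.random.default_rng(3)


# ---------------------------------------------------------------------------
# patch embedding / merging
# ---------------------------------------------------------------------------

def test_patch_embed_single_patch_and_channel_check(rng):
    pe = PatchEmbed(embed=8, rng=rng)
    out = pe(rng.standard_normal((1, 3, 4, 4)).astype(np.float32))
    assert out.shape == (1, 8, 1, 1)
    with pytest.raises(ValueError):
        pe(rng.standard_normal((1, 1, 4, 4)).astype(np.float32))


def test_patch_embed_downsamples_by_four_and_pads(rng):
    pe = PatchEmbed(embed=8, rng=rng)
    assert pe(rng.standard_normal((1, 3, 64, 64)).astype(np.float32)).shape == (1, 8, 16, 16)
    # non-divisible side is right/bottom zero-padded before embedding
    assert pe(rng.standard_normal((1, 3, 62, 61)).astype(np.float32)).shape == (1, 8, 16, 16)


def test_patch_merge_shapes_and_partition(rng):
    pm = PatchMerging(dim=4, rng=rng)
    out = pm(rng.standard_normal((1, 4, 8, 8)).astype(np.float32))
    assert out.shape == (1, 8, 4, 4)
    # partition property: the four stride-2 sub-grids tile the input exactly
    idx = np.arange(64).reshape(8, 8)
    subs = [idx[0::2, 0::2], idx[0::2, 1::2], idx[1::2, 0::2], idx[1::2, 1::2]]
    assert sorted(np.concatenate([s.ravel() for s in subs]).tolist()) == list(range(64))


def test_patch_merge_hand_worked_2x2_case(rng):
    """2x2x1 input, identity reduction: output = first two entries of the
    layer-normalised (ee, eo, oe, oo) concatenation."""
    pm = PatchMerging(dim=1, rng=rng)
    eye = np.zeros((4, 2), np.float32)
    eye[0, 0] = eye[1, 1] = 1.0
    pm.reduction.weight.data = eye
    a, b, c, d = 1.0, -2.0, 3.0, 0.5
    x = np.array([[a, b], [c, d]], np.float32).reshape(1, 1, 2, 2)
    out = pm(x).data.reshape(2)
    v = np.array([a, b, c, d])
    norm = (v - v.mean()) / np.sqrt(v.var() + 1e-5)
    assert np.allclose(out, norm[:2], atol=1e-5)


# ---------------------------------------------------------------------------
# attention primitives
# ---------------------------------------------------------------------------

def test_scaled_attention_single_token_returns_value_row():
    X = np.array([[1.0, 2.0]], np.float32)
    W = np.eye(2, dtype=np.float32)
    out = scaled_attention(X, W, W, W * 3.0)
    assert np.allclose(out.data, X @ (W * 3.0))


def test_scaled_attention_matches_explicit_formula():
    X = np.array([[1.0, 0.5], [-1.0, 2.0]], np.float32)
    Wq = np.array([[0.2, -0.1], [0.4, 0.3]], np.float32)
    Wk = np.array([[-0.3, 0.5], [0.1, 0.2]], np.float32)
    Wv = np.array([[1.0, 0.0], [0.0, -1.0]], np.float32)
    Q, K, V = X @ Wq, X @ Wk, X @ Wv
    logits = Q @ K.T / math.sqrt(2)
    e = np.exp(logits)
    A = e / e.sum(axis=1, keepdims=True)
    assert np.allclose(scaled_attention(X, Wq, Wk, Wv).data, A @ V, atol=1e-6)


def test_scaled_attention_bias_shift_invariance_and_row_sums():
    X = RNG.standard_normal((5, 4)).astype(np.float32)
    W = [RNG.standard_normal((4, 4)).astype(np.float32) for _ in range(3)]
    bias = RNG.standard_normal((5, 5)).astype(np.float32)
    out1 = scaled_attention(X, *W, bias=bias)
    out2 = scaled_attention(X, *W, bias=bias + 7.3)
    assert np.allclose(out1.data, out2.data, atol=1e-5)
    # softmax rows sum to 1
    Q, K = Tensor(X) @ Tensor(W[0]), Tensor(X) @ Tensor(W[1])
    logits = (Q @ K.transpose(1, 0)) * np.float32(1 / math.sqrt(4)) + bias
    rows = T.softmax(logits, axis=-1).data.sum(axis=-1)
    assert np.allclose(rows, 1.0, atol=1e-5)


def test_scaled_attention_rejects_nonpositive_d():
    X = np.ones((2, 2), np.float32)
    with pytest.raises(ValueError):
        scaled_attention(X, X, X, X, d=0)


def test_multi_head_reduces_to_single_head_with_identity_fusion():
    X = RNG.standard_normal((4, 6)).astype(np.float32)
    W = [RNG.standard_normal((6, 6)).astype(np.float32) for _ in range(3)]
    out = multi_head_attention(X, *W, np.eye(6, dtype=np.float32), heads=1)
    assert np.allclose(out.data, scaled_attention(X, *W).data, atol=1e-5)


def test_multi_head_matches_per_head_loop_oracle():
    n, dm, h = 4, 6, 2
    X = RNG.standard_normal((n, dm)).astype(np.float32)
    Wq, Wk, Wv, Wo = [RNG.standard_normal((dm, dm)).astype(np.float32) for _ in range(4)]
    got = multi_head_attention(X, Wq, Wk, Wv, Wo, heads=h).data
    Q, K, V = X @ Wq, X @ Wk, X @ Wv
    dh = dm // h
    heads = []
    for i in range(h):
        q, k, v = (M[:, i * dh : (i + 1) * dh] for M in (Q, K, V))
        logits = q @ k.T / math.sqrt(dh)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        heads.append((e / e.sum(axis=1, keepdims=True)) @ v)
    assert np.abs(got - np.concatenate(heads, axis=1) @ Wo).max() < 1e-5


def test_multi_head_rejects_indivisible_dim():
    X = np.ones((2, 6), np.float32)
    W = np.eye(6, dtype=np.float32)
    with pytest.raises(ValueError):
        multi_head_attention(X, W, W, W, W, heads=4)


# ---------------------------------------------------------------------------
# windowed attention
# ---------------------------------------------------------------------------

def _win_attn(dim=8, heads=2, ws=4, bias=False):
    return WindowAttention(dim, heads, ws, np.random.default_rng(5),
                           learnable_bias=bias)


def test_w_msa_full_window_equals_global_attention():
    attn = _win_attn(ws=6)
    x = RNG.standard_normal((1, 6, 6, 8)).astype(np.float32)
    windowed = w_msa(Tensor(x), attn).data.reshape(36, 8)
    global_ = multi_head_attention(
        x.reshape(36, 8), attn.q.weight.data, attn.k.weight.data,
        attn.v.weight.data, attn.proj.weight.data, heads=2,
    ).data
    assert np.allclose(windowed, global_, atol=1e-5)


def test_w_msa_four_windows_and_locality():
    ws = 4
    attn = _win_attn(ws=ws, bias=True)
    attn.bias_table.data = RNG.standard_normal(attn.bias_table.shape).astype(np.float32)
    x = RNG.standard_normal((1, 2 * ws, 2 * ws, 8)).astype(np.float32)
    assert window_partition(Tensor(x), ws).shape[0] == 4
    y1 = w_msa(Tensor(x), attn).data
    x2 = x.copy()
    x2[0, :ws, :ws] += RNG.standard_normal((ws, ws, 8)).astype(np.float32)
    y2 = w_msa(Tensor(x2), attn).data
    # only the perturbed window changes; the other three are bit-identical
    assert not np.array_equal(y1[0, :ws, :ws], y2[0, :ws, :ws])
    assert np.array_equal(y1[0, :ws, ws:], y2[0, :ws, ws:])
    assert np.array_equal(y1[0, ws:, :], y2[0, ws:, :])


def test_window_batch_permutation_consistency():
    attn = _win_attn(bias=True)
    attn.bias_table.data = RNG.standard_normal(attn.bias_table.shape).astype(np.float32)
    wins = RNG.standard_normal((6, 16, 8)).astype(np.float32)
    perm = np.array([3, 1, 5, 0, 2, 4])
    assert np.allclose(
        attn(Tensor(wins)).data[perm], attn(Tensor(wins[perm])).data, atol=1e-6
    )


def test_sw_msa_zero_shift_equals_w_msa():
    attn = _win_attn()
    x = Tensor(RNG.standard_normal((1, 8, 8, 8)).astype(np.float32))
    assert np.array_equal(sw_msa(x, attn, shift=0).data, w_msa(x, attn).data)


def test_cyclic_shift_roundtrip_is_identity():
    x = Tensor(RNG.standard_normal((1, 8, 8, 3)).astype(np.float32))
    y = T.roll2d(T.roll2d(x, (-2, -2), (1, 2)), (2, 2), (1, 2))
    assert np.array_equal(x.data, y.data)


def test_sw_msa_region_isolation():
    """With the shift mask, a token's output depends only on tokens from its
    own pre-shift region: perturbing one region leaves all others fixed."""
    ws, shift = 4, 2
    attn = _win_attn(ws=ws)
    side = 2 * ws
    x = RNG.standard_normal((1, side, side, 8)).astype(np.float32)
    y1 = sw_msa(Tensor(x), attn, shift=shift).data
    x2 = x.copy()
    x2[0, :shift, :shift] += 1.0  # one corner region of the original map
    y2 = sw_msa(Tensor(x2), attn, shift=shift).data
    changed = np.zeros((side, side), bool)
    changed[:shift, :shift] = True
    assert np.array_equal(y1[0][~changed], y2[0][~changed])
    assert not np.array_equal(y1[0][changed], y2[0][changed])


def test_sw_msa_rejects_shift_not_below_window():
    attn = _win_attn()
    x = Tensor(np.zeros((1, 8, 8, 8), np.float32))
    with pytest.raises(ValueError):
        sw_msa(x, attn, shift=4)


# ---------------------------------------------------------------------------
# transformer block and full backbone
# ---------------------------------------------------------------------------

def test_block_with_zeroed_projections_is_identity(rng):
    blk = TransformerBlock(8, 2, 4, 0, rng)
    blk.attn.proj.weight.data[:] = 0
    blk.mlp.fc2.weight.data[:] = 0
    x = RNG.standard_normal((1, 8, 8, 8)).astype(np.float32)
    assert np.allclose(blk(Tensor(x)).data, x, atol=1e-6)


def test_block_deterministic_without_drop_path(rng):
    blk = TransformerBlock(8, 2, 4, 2, rng, drop_path=0.0)
    x = Tensor(RNG.standard_normal((2, 8, 8, 8)).astype(np.float32))
    assert np.array_equal(blk(x).data, blk(x).data)


def test_w_sw_pair_matches_straightline_composition(rng):
    """A W->SW block pair equals the explicit six-step reference wiring:
    LN, attention, residual, LN, MLP, residual — twice."""
    b1 = TransformerBlock(8, 2, 4, 0, rng)
    b2 = TransformerBlock(8, 2, 4, 2, rng)
    x = Tensor(RNG.standard_normal((1, 16, 16, 8)).astype(np.float32))
    got = b2(b1(x)).data

    y = x + w_msa(b1.norm1(x), b1.attn)
    y = y + b1.mlp(b1.norm2(y))
    y = y + sw_msa(b2.norm1(y), b2.attn, shift=2)
    y = y + b2.mlp(b2.norm2(y))
    assert np.allclose(got, y.data, atol=1e-5)


TINY = BackboneConfig(embed_channels=8, depths=(2, 2, 2, 2), heads=(1, 2, 4, 8),
                      drop_path=0.0)


@pytest.mark.parametrize("side,expect", [
    (128, [(8, 32, 32), (16, 16, 16), (32, 8, 8), (64, 4, 4)]),
    (320, [(8, 80, 80), (16, 40, 40), (32, 20, 20), (64, 10, 10)]),
])
def test_backbone_spatial_schedule(side, expect):
    """side(Ck) = input/4/2^(k-1); channels double at each merge."""
    bb = Backbone(TINY, input_side=side, rng=np.random.default_rng(0))
    x = np.random.default_rng(1).standard_normal((1, 3, side, side)).astype(np.float32)
    with T.no_grad():
        out = bb(x)
    got = [out[f"C{k}"].shape[1:] for k in range(1, 5)]
    assert got == expect
    assert bb.stage_dims[-1] == 8 * bb.stage_dims[0]


def test_backbone_rejects_small_input_and_odd_depths():
    bb = Backbone(TINY, input_side=64, rng=np.random.default_rng(0))
    with pytest.raises(ValueError):
        bb(np.zeros((1, 3, 16, 16), np.float32))
    with pytest.raises(ValueError):
        BackboneConfig(depths=(2, 3, 2, 2)).validate()


def test_backbone_deterministic(rng):
    bb = Backbone(TINY, input_side=64, rng=rng)
    x = RNG.standard_normal((1, 3, 64, 64)).astype(np.float32)
    with T.no_grad():
        a = bb(x)
        b = bb(x)
    for k in a:
        assert np.array_equal(a[k].data, b[k].data)
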