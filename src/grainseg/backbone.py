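"""Hierarchical windowed-attention backbone producing stage maps C1-C4.

The extractor tokenises the image with a stride-4 patch embedding, then runs
four stages of window-restricted multi-head self-attention blocks, halving the
spatial side and doubling the channel count between stages with a patch-merge
layer (96 -> 192 -> 384 -> 768 at the default width).  Within a stage, blocks
alternate between plain windowed attention (W-MSA) and shifted-window
attention (SW-MSA); the shift is half a window, and a mask forbids attention
between tokens that were not neighbours before the cyclic shift.

By default each stage's window is half its map side, so W-MSA sees exactly
four windows and SW-MSA's shifted partition covers nine regions; a fixed
window size (with boundary padding) is available through the config.

Self-attention follows softmax(Q K^T / sqrt(d) + B) V with Q, K, V linear
projections of the tokens and B an additive logit bias; multi-head attention
splits the model dimension across heads, attends per head, concatenates and
fuses with an output projection.
"""

from __future__ import annotations

import functools
import math

import numpy as np

from . import tensor as T
from .config import BackboneConfig
from .nn import DropPath, LayerNorm, Linear, Mlp, Module, parameter
from .tensor import Tensor

__all__ = [
    "scaled_attention",
    "multi_head_attention",
    "window_partition",
    "window_reverse",
    "w_msa",
    "sw_msa",
    "PatchEmbed",
    "PatchMerging",
    "WindowAttention",
    "TransformerBlock",
    "Backbone",
]

_NEG = np.float32(-1e9)  # additive mask value: exp() underflows to exactly 0
_ATTN_CHUNK = 1 << 26  # max elements of one attention-logit block


# ---------------------------------------------------------------------------
# functional attention primitives
# ---------------------------------------------------------------------------

def scaled_attention(X, Wq, Wk, Wv, bias=None, d: int | None = None) -> Tensor:
    """Single-head scaled dot-product attention on a (tokens, dim) matrix.

    Returns softmax(Q K^T / sqrt(d) + bias) V with Q = X Wq, K = X Wk,
    V = X Wv.  ``d`` defaults to the key dimensionality.
    """
    X, Wq, Wk, Wv = map(T.as_tensor, (X, Wq, Wk, Wv))
    Q, K, V = X @ Wq, X @ Wk, X @ Wv
    if d is None:
        d = K.shape[-1]
    if d <= 0:
        raise ValueError(f"key dimensionality must be positive, got {d}")
    logits = (Q @ K.transpose(1, 0)) * np.float32(1.0 / math.sqrt(d))
    if bias is not None:
        logits = logits + (bias if isinstance(bias, Tensor) else np.asarray(bias, np.float32))
    return T.softmax(logits, axis=-1) @ V


def multi_head_attention(X, Wq, Wk, Wv, Wo, heads: int, bias=None) -> Tensor:
    """Multi-head attention on a (tokens, dim) matrix.

    The model dimension is split evenly across heads (the per-head split
    matrices are coordinate selections of Q, K, V), each head attends with
    scale 1/sqrt(dim/heads), the head outputs are concatenated and fused by
    the output projection Wo.  ``bias`` may be (tokens, tokens), broadcast
    over heads, or (heads, tokens, tokens).
    """
    X, Wq, Wk, Wv, Wo = map(T.as_tensor, (X, Wq, Wk, Wv, Wo))
    n, dm = X.shape
    if heads < 1:
        raise ValueError("heads must be >= 1")
    if dm % heads != 0:
        raise ValueError(f"model dim {dm} not divisible by {heads} heads")
    dh = dm // heads
    Q = (X @ Wq).reshape(n, heads, dh).transpose(1, 0, 2)
    K = (X @ Wk).reshape(n, heads, dh).transpose(1, 0, 2)
    V = (X @ Wv).reshape(n, heads, dh).transpose(1, 0, 2)
    logits = (Q @ K.transpose(0, 2, 1)) * np.float32(1.0 / math.sqrt(dh))
    if bias is not None:
        b = bias if isinstance(bias, Tensor) else T.as_tensor(bias)
        logits = logits + b
    out = T.softmax(logits, axis=-1) @ V  # (heads, n, dh)
    return out.transpose(1, 0, 2).reshape(n, dm) @ Wo


# ---------------------------------------------------------------------------
# window bookkeeping
# ---------------------------------------------------------------------------

def window_partition(x: Tensor, ws: int) -> Tensor:
    """(B, H, W, C) -> (B * nH * nW, ws*ws, C); H, W must divide by ws."""
    B, H, W, C = x.shape
    x = x.reshape(B, H // ws, ws, W // ws, ws, C)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(B * (H // ws) * (W // ws), ws * ws, C)


def window_reverse(wins: Tensor, ws: int, B: int, H: int, W: int) -> Tensor:
    """Inverse of :func:`window_partition`."""
    C = wins.shape[-1]
    x = wins.reshape(B, H // ws, W // ws, ws, ws, C)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(B, H, W, C)


def _pad_hw(x: Tensor, ws: int) -> tuple[Tensor, int, int]:
    """Right/bottom zero-pad a (B, H, W, C) map so ws divides both sides."""
    B, H, W, C = x.shape
    Hp = int(math.ceil(H / ws)) * ws
    Wp = int(math.ceil(W / ws)) * ws
    if (Hp, Wp) == (H, W):
        return x, H, W
    x = x.transpose(0, 3, 1, 2)
    x = T.pad2d(x, (0, Hp - H, 0, Wp - W))
    return x.transpose(0, 2, 3, 1), Hp, Wp


@functools.lru_cache(maxsize=32)
def relative_position_index(ws: int) -> np.ndarray:
    """(ws^2, ws^2) index into a (2ws-1)^2 table of relative token offsets."""
    coords = np.stack(np.meshgrid(np.arange(ws), np.arange(ws), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :] + ws - 1
    return (rel[0] * (2 * ws - 1) + rel[1]).astype(np.int32)


@functools.lru_cache(maxsize=32)
def window_region_ids(H: int, W: int, ws: int, shift: int) -> np.ndarray:
    """(num_windows, ws^2) pre-shift region label of each token.

    After the cyclic shift, tokens inside one window may originate from up to
    four different regions of the map; attention between tokens with
    different labels is masked out.  On a map of side 2*ws the shifted
    partition corresponds to nine distinct regions.
    """
    img = np.zeros((H, W), dtype=np.int8)
    cnt = 0
    for hs in (slice(0, H - ws), slice(H - ws, H - shift), slice(H - shift, H)):
        for wsl in (slice(0, W - ws), slice(W - ws, W - shift), slice(W - shift, W)):
            img[hs, wsl] = cnt
            cnt += 1
    return (
        img.reshape(H // ws, ws, W // ws, ws)
        .transpose(0, 2, 1, 3)
        .reshape(-1, ws * ws)
    )


def shift_attention_mask(H: int, W: int, ws: int, shift: int) -> np.ndarray:
    """(num_windows, ws^2, ws^2) additive mask for shifted-window attention
    (0 within a region, -1e9 across regions)."""
    ids = window_region_ids(H, W, ws, shift)
    return np.where(
        ids[:, None, :] != ids[:, :, None], _NEG, np.float32(0.0)
    ).astype(np.float32)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class WindowAttention(Module):
    """Multi-head self-attention restricted to ws x ws token windows.

    Carries a learnable relative-position bias table indexed by token offset
    (initialised to zero; ``learnable_bias=False`` fixes the bias at zero,
    used by the oracle tests).
    """

    def __init__(self, dim: int, heads: int, window_size: int,
                 rng: np.random.Generator, learnable_bias: bool = True):
        super().__init__()
        if dim % heads != 0:
            raise ValueError(f"dim {dim} not divisible by {heads} heads")
        self.dim = dim
        self.heads = heads
        self.window_size = window_size
        self.q = Linear(dim, dim, rng, bias=False)
        self.k = Linear(dim, dim, rng, bias=False)
        self.v = Linear(dim, dim, rng, bias=False)
        self.proj = Linear(dim, dim, rng)
        self.learnable_bias = learnable_bias
        if learnable_bias:
            n_off = (2 * window_size - 1) ** 2
            self.bias_table = parameter(np.zeros((n_off, heads)))
        else:
            self.bias_table = None

    def forward(self, wins: Tensor, region_ids: np.ndarray | None = None) -> Tensor:
        """wins: (G, n, C) stacked windows.

        ``region_ids`` is an optional (G, n) or (n,) integer labelling; token
        pairs with different labels are masked out of each other's softmax
        (the shifted-window mask).  Attention logits are processed in blocks
        of query rows so that no (n, n) matrix larger than a fixed budget is
        ever materialised — at the default 640-px config the stage-1 windows
        hold 6400 tokens and full matrices would not fit in memory.
        """
        G, n, C = wins.shape
        h, dh = self.heads, self.dim // self.heads
        scale = np.float32(1.0 / math.sqrt(dh))
        idx = relative_position_index(self.window_size) if self.bias_table is not None else None
        if region_ids is not None:
            region_ids = np.asarray(region_ids)
            if region_ids.ndim == 1:
                region_ids = np.broadcast_to(region_ids, (G, n))
        qchunk = min(n, max(1, _ATTN_CHUNK // max(1, 8 * h * n)))
        gchunk = max(1, _ATTN_CHUNK // max(1, h * n * qchunk))
        outs = []
        for glo in range(0, G, gchunk):
            ghi = min(G, glo + gchunk)
            xw = wins[(slice(glo, ghi),)]
            Q = self.q(xw).reshape(ghi - glo, n, h, dh).transpose(0, 2, 1, 3)
            K = self.k(xw).reshape(ghi - glo, n, h, dh).transpose(0, 2, 1, 3)
            V = self.v(xw).reshape(ghi - glo, n, h, dh).transpose(0, 2, 1, 3)
            Kt = K.transpose(0, 1, 3, 2)
            rows = []
            for qlo in range(0, n, qchunk):
                qhi = min(n, qlo + qchunk)
                Qc = Q[(slice(None), slice(None), slice(qlo, qhi))]
                logits = (Qc @ Kt) * scale  # (g, h, q, n)
                if idx is not None:
                    bias = self.bias_table[idx[qlo:qhi]]  # (q, n, h)
                    logits = logits + bias.transpose(2, 0, 1)
                if region_ids is not None:
                    m = np.where(
                        region_ids[glo:ghi, None, qlo:qhi, None]
                        != region_ids[glo:ghi, None, None, :],
                        _NEG,
                        np.float32(0.0),
                    )
                    logits = logits + m
                rows.append(T.softmax(logits, axis=-1) @ V)  # (g, h, q, dh)
            y = rows[0] if len(rows) == 1 else T.concat(rows, axis=2)
            outs.append(y.transpose(0, 2, 1, 3).reshape(ghi - glo, n, C))
        out = outs[0] if len(outs) == 1 else T.concat(outs, axis=0)
        return self.proj(out)


def w_msa(x: Tensor, attn: WindowAttention, window_size: int | None = None) -> Tensor:
    """Windowed attention on a (B, H, W, C) map; shape-preserving."""
    ws = window_size or attn.window_size
    H, W = x.shape[1], x.shape[2]
    xp, Hp, Wp = _pad_hw(x, ws)
    wins = window_partition(xp, ws)
    out = attn(wins)
    out = window_reverse(out, ws, x.shape[0], Hp, Wp)
    if (Hp, Wp) != (H, W):
        out = out[(slice(None), slice(0, H), slice(0, W))]
    return out


def sw_msa(x: Tensor, attn: WindowAttention, window_size: int | None = None,
           shift: int | None = None) -> Tensor:
    """Shifted-window attention: cyclic shift, masked windowed attention,
    reverse shift.  ``shift`` defaults to half the window."""
    ws = window_size or attn.window_size
    if shift is None:
        shift = ws // 2
    if shift >= ws:
        raise ValueError(f"shift {shift} must be smaller than window {ws}")
    if shift == 0:
        return w_msa(x, attn, ws)
    H, W = x.shape[1], x.shape[2]
    xp, Hp, Wp = _pad_hw(x, ws)
    xp = T.roll2d(xp, (-shift, -shift), (1, 2))
    ids = window_region_ids(Hp, Wp, ws, shift)
    wins = window_partition(xp, ws)
    out = attn(wins, region_ids=np.tile(ids, (x.shape[0], 1)))
    out = window_reverse(out, ws, x.shape[0], Hp, Wp)
    out = T.roll2d(out, (shift, shift), (1, 2))
    if (Hp, Wp) != (H, W):
        out = out[(slice(None), slice(0, H), slice(0, W))]
    return out


class PatchEmbed(Module):
    """Stride-4 tokenisation: 4x4 conv to ``embed`` channels, then layer
    normalisation over the channel axis (flatten -> normalise -> restore)."""

    def __init__(self, embed: int, rng: np.random.Generator, in_ch: int = 3):
        super().__init__()
        from .nn import Conv2d  # local import avoids a cycle in docs builds

        self.in_ch = in_ch
        self.conv = Conv2d(in_ch, embed, kernel=4, rng=rng, stride=4)
        self.norm = LayerNorm(embed)

    def forward(self, x) -> Tensor:
        x = T.as_tensor(x)
        if x.ndim != 4 or x.shape[1] != self.in_ch:
            raise ValueError(
                f"expected (B, {self.in_ch}, H, W) input, got {x.shape}"
            )
        H, W = x.shape[2], x.shape[3]
        ph, pw = (-H) % 4, (-W) % 4
        if ph or pw:
            x = T.pad2d(x, (0, ph, 0, pw))
        y = self.conv(x)  # (B, C, H/4, W/4)
        t = y.transpose(0, 2, 3, 1)
        t = self.norm(t)
        return t.transpose(0, 3, 1, 2)


class PatchMerging(Module):
    """Stride-2 spatial subsampling that doubles the channel count.

    The four interval-2 sub-grids (even/even, even/odd, odd/even, odd/odd)
    are concatenated along channels (4C), layer-normalised, and linearly
    mapped to 2C.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.dim = dim
        self.norm = LayerNorm(4 * dim)
        self.reduction = Linear(4 * dim, 2 * dim, rng, bias=False)

    def forward(self, x) -> Tensor:
        x = T.as_tensor(x)  # (B, C, H, W)
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            x = T.pad2d(x, (0, H % 2, 0, W % 2))
        parts = [
            x[(slice(None), slice(None), slice(0, None, 2), slice(0, None, 2))],
            x[(slice(None), slice(None), slice(0, None, 2), slice(1, None, 2))],
            x[(slice(None), slice(None), slice(1, None, 2), slice(0, None, 2))],
            x[(slice(None), slice(None), slice(1, None, 2), slice(1, None, 2))],
        ]
        y = T.concat(parts, axis=1)  # (B, 4C, H/2, W/2)
        t = y.transpose(0, 2, 3, 1)
        t = self.reduction(self.norm(t))
        return t.transpose(0, 3, 1, 2)


class TransformerBlock(Module):
    """One attention block: LN -> (S)W-MSA -> drop-path -> residual, then
    LN -> MLP -> drop-path -> residual.  Blocks are used in W/SW pairs."""

    def __init__(self, dim: int, heads: int, window_size: int, shift: int,
                 rng: np.random.Generator, mlp_ratio: float = 4.0,
                 drop_path: float = 0.0, learnable_bias: bool = True):
        super().__init__()
        if shift >= window_size:
            raise ValueError("shift must be smaller than window_size")
        self.shift = shift
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, window_size, rng, learnable_bias)
        self.drop_path = DropPath(drop_path, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(round(mlp_ratio * dim)), rng)

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, H, W, C) channels-last token map."""
        y = self.norm1(x)
        if self.shift:
            y = sw_msa(y, self.attn, shift=self.shift)
        else:
            y = w_msa(y, self.attn)
        x = x + self.drop_path(y)
        return x + self.drop_path(self.mlp(self.norm2(x)))


class Backbone(Module):
    """Four-stage windowed-attention feature extractor.

    ``forward`` maps a normalised (B, 3, H, W) batch to the stage dict
    {"C1": (B, C, H/4, W/4), ..., "C4": (B, 8C, H/32, W/32)}.  Window sizes
    are fixed at construction from ``input_side`` (half of each stage's map
    side unless the config pins them), so parameter shapes are stable for
    checkpointing.
    """

    def __init__(self, cfg: BackboneConfig | None = None, input_side: int = 640,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg = cfg or BackboneConfig()
        cfg.validate()
        if input_side < 32:
            raise ValueError("input side below 32 px: stage-4 map would vanish")
        rng = rng or np.random.default_rng(0)
        n_stages = len(cfg.depths)
        total_depth = sum(cfg.depths)
        rates = (
            np.linspace(0.0, cfg.drop_path, total_depth)
            if cfg.drop_path > 0
            else np.zeros(total_depth)
        )
        self.patch_embed = PatchEmbed(cfg.embed_channels, rng)
        self.stage_dims = [cfg.embed_channels * 2**k for k in range(n_stages)]
        self.window_sizes = []
        blocks: list[Module] = []
        merges: list[Module] = []
        bi = 0
        side = input_side // cfg.patch_size
        for k in range(n_stages):
            if k > 0:
                merges.append(PatchMerging(self.stage_dims[k - 1], rng))
                side = (side + 1) // 2
            ws = cfg.window_size or max(1, side // 2)
            self.window_sizes.append(ws)
            for j in range(cfg.depths[k]):
                shift = 0 if j % 2 == 0 else ws // 2
                blocks.append(
                    TransformerBlock(
                        self.stage_dims[k], cfg.heads[k], ws, shift, rng,
                        mlp_ratio=cfg.mlp_ratio, drop_path=float(rates[bi]),
                        learnable_bias=cfg.learnable_bias,
                    )
                )
                bi += 1
        self.blocks = blocks
        self.merges = merges

    def forward(self, x) -> dict[str, Tensor]:
        x = T.as_tensor(x)
        if x.shape[-1] < 32 or x.shape[-2] < 32:
            raise ValueError("input smaller than 32 x 32 px")
        cfg = self.cfg
        t = self.patch_embed(x).transpose(0, 2, 3, 1)  # (B, h, w, C)
        out: dict[str, Tensor] = {}
        bi = 0
        for k in range(len(cfg.depths)):
            if k > 0:
                t = self.merges[k - 1](t.transpose(0, 3, 1, 2)).transpose(0, 2, 3, 1)
            for _ in range(cfg.depths[k]):
                t = self.blocks[bi](t)
                bi += 1
            out[f"C{k + 1}"] = t.transpose(0, 3, 1, 2)
        return out
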