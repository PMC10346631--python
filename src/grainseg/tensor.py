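"""A compact reverse-mode automatic-differentiation engine over NumPy arrays.

Every trainable computation in this package (windowed attention, convolutions,
layer normalisation, the losses) is expressed with the :class:`Tensor` wrapper
defined here.  The engine is tape-based: each operation records its parents and
a backward closure; :meth:`Tensor.backward` walks the tape in reverse
topological order.  Only the operations this package needs are provided, and
the expensive ones (convolution, layer norm, softmax, the fused losses) carry
hand-derived backward rules rather than being composed from primitives, to
keep training on a single CPU tractable.

Gradients accumulate in float32; shapes follow NumPy broadcasting, with
broadcast axes summed out on the way back.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "as_tensor",
    "concat",
    "relu",
    "gelu",
    "tanh",
    "sigmoid",
    "softmax",
    "layer_norm",
    "linear",
    "conv2d",
    "pad2d",
    "crop2d",
    "roll2d",
    "upsample2x",
    "smooth_l1",
    "softmax_cross_entropy",
    "binary_cross_entropy_with_logits",
]

_GRAD_ENABLED = [True]


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


@contextlib.contextmanager
def no_grad():
    """Context manager disabling tape recording (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd ------------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
            # free the tape as we go; parents keep their own closures
            node._backward = None
            node._parents = ()

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, lambda a, b, g: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, lambda a, b, g: (g, -g))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply, lambda a, b, g: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(
            self, other, np.divide, lambda a, b, g: (g / b, -g * a / (b * b))
        )

    def __neg__(self):
        return self * -1.0

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _make(self.data @ other.data, (self, other))
        if out._parents:
            a, b = self, other

            def bwd():
                g = out.grad
                if a.requires_grad or a._parents:
                    ga = g @ np.swapaxes(b.data, -1, -2)
                    a._accum(_unbroadcast(ga, a.data.shape))
                if b.requires_grad or b._parents:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                    b._accum(_unbroadcast(gb, b.data.shape))

            out._backward = bwd
        return out

    def __getitem__(self, key):
        out = _make(self.data[key], (self,))
        if out._parents:
            src = self

            def bwd():
                g = np.zeros_like(src.data)
                np.add.at(g, key, out.grad)
                src._accum(g)

            out._backward = bwd
        return out

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out._parents:
            src = self
            out._backward = lambda: src._accum(out.grad.reshape(src.data.shape))
        return out

    def transpose(self, *perm):
        if len(perm) == 1 and isinstance(perm[0], (tuple, list)):
            perm = tuple(perm[0])
        out = _make(self.data.transpose(perm), (self,))
        if out._parents:
            src = self
            inv = np.argsort(perm)
            out._backward = lambda: src._accum(out.grad.transpose(inv))
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out._parents:
            src = self

            def bwd():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                src._accum(np.broadcast_to(g, src.data.shape).copy())

            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _track(*tensors: Tensor) -> bool:
    return is_grad_enabled() and any(
        t.requires_grad or t._parents or t._backward is not None for t in tensors
    )


def _make(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    if is_grad_enabled() and any(
        p.requires_grad or p._parents or p._backward is not None for p in parents
    ):
        out._parents = tuple(parents)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


def _binary(a, b, fwd, bwd_fn):
    a, b = as_tensor(a), as_tensor(b)
    out = _make(fwd(a.data, b.data), (a, b))
    if out._parents:

        def bwd():
            ga, gb = bwd_fn(a.data, b.data, out.grad)
            if a.requires_grad or a._parents:
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad or b._parents:
                b._accum(_unbroadcast(gb, b.data.shape))

        out._backward = bwd
    return out


def _unary(x, fwd_val, grad_local):
    x = as_tensor(x)
    out = _make(fwd_val, (x,))
    if out._parents:
        out._backward = lambda: x._accum(out.grad * grad_local())
    return out


# ---------------------------------------------------------------------------
# elementwise nonlinearities
# ---------------------------------------------------------------------------

def relu(x) -> Tensor:
    x = as_tensor(x)
    y = np.maximum(x.data, 0.0)
    return _unary(x, y, lambda: (x.data > 0).astype(np.float32))


def tanh(x) -> Tensor:
    x = as_tensor(x)
    y = np.tanh(x.data)
    return _unary(x, y, lambda: 1.0 - y * y)


def sigmoid(x) -> Tensor:
    x = as_tensor(x)
    y = _sigmoid_np(x.data)
    return _unary(x, y, lambda: y * (1.0 - y))


def _sigmoid_np(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


_GELU_C = np.float32(np.sqrt(2.0 / np.pi))


def gelu(x) -> Tensor:
    """Gaussian error linear unit (tanh approximation)."""
    x = as_tensor(x)
    v = x.data
    inner = _GELU_C * (v + 0.044715 * v**3)
    t = np.tanh(inner)
    y = 0.5 * v * (1.0 + t)

    def local():
        dt = (1.0 - t * t) * _GELU_C * (1.0 + 3 * 0.044715 * v * v)
        return 0.5 * (1.0 + t) + 0.5 * v * dt

    return _unary(x, y, local)


def softmax(x, axis: int = -1) -> Tensor:
    """Numerically stable softmax with a fused backward rule."""
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = _make(y, (x,))
    if out._parents:

        def bwd():
            g = out.grad
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accum(y * (g - dot))

        out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# normalisation / linear algebra
# ---------------------------------------------------------------------------

def layer_norm(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = _make(xhat * gamma.data + beta.data, (x, gamma, beta))
    if out._parents:
        n = x.data.shape[-1]

        def bwd():
            g = out.grad
            if gamma.requires_grad or gamma._parents:
                gamma._accum(
                    _unbroadcast(g * xhat, gamma.data.shape).reshape(gamma.data.shape)
                )
            if beta.requires_grad or beta._parents:
                beta._accum(_unbroadcast(g, beta.data.shape).reshape(beta.data.shape))
            if x.requires_grad or x._parents:
                gx = g * gamma.data
                s1 = gx.sum(axis=-1, keepdims=True)
                s2 = (gx * xhat).sum(axis=-1, keepdims=True)
                x._accum(inv * (gx - s1 / n - xhat * s2 / n))

        out._backward = bwd
    return out


def linear(x, w, b=None) -> Tensor:
    """x @ w (+ b), with w of shape (in, out)."""
    out = as_tensor(x) @ as_tensor(w)
    if b is not None:
        out = out + as_tensor(b)
    return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in ts], axis=axis), ts)
    if out._parents:
        sizes = [t.data.shape[axis] for t in ts]
        splits = np.cumsum(sizes)[:-1]

        def bwd():
            pieces = np.split(out.grad, splits, axis=axis)
            for t, g in zip(ts, pieces):
                if t.requires_grad or t._parents:
                    t._accum(g)

        out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# spatial ops on (B, C, H, W) maps
# ---------------------------------------------------------------------------

def pad2d(x, pad: tuple[int, int, int, int]) -> Tensor:
    """Zero-pad (top, bottom, left, right) the last two axes."""
    x = as_tensor(x)
    t, b, l, r = pad
    if t == b == l == r == 0:
        return x
    width = [(0, 0)] * (x.ndim - 2) + [(t, b), (l, r)]
    out = _make(np.pad(x.data, width), (x,))
    if out._parents:
        H, W = x.data.shape[-2:]
        sl = (Ellipsis, slice(t, t + H), slice(l, l + W))
        out._backward = lambda: x._accum(out.grad[sl])
    return out


def crop2d(x, h: int, w: int) -> Tensor:
    """Keep the top-left h × w corner of the last two axes."""
    x = as_tensor(x)
    if x.data.shape[-2] == h and x.data.shape[-1] == w:
        return x
    return x[(Ellipsis, slice(0, h), slice(0, w))]


def roll2d(x, shifts: tuple[int, int], axes: tuple[int, int]) -> Tensor:
    """Cyclic roll over two axes (used by shifted-window attention)."""
    x = as_tensor(x)
    out = _make(np.roll(x.data, shifts, axis=axes), (x,))
    if out._parents:
        inv = (-shifts[0], -shifts[1])
        out._backward = lambda: x._accum(np.roll(out.grad, inv, axis=axes))
    return out


def upsample2x(x, mode: str = "nearest") -> Tensor:
    """Double the spatial side of a (B, C, H, W) map.

    `bilinear` uses align_corners=False convention; for an exact factor of two
    this reduces to a fixed 4-tap stencil, implemented via zero-padded shifts.
    """
    x = as_tensor(x)
    if mode == "nearest":
        out = _make(x.data.repeat(2, axis=-2).repeat(2, axis=-1), (x,))
        if out._parents:
            B_, C_, H, W = out.data.shape

            def bwd():
                g = out.grad.reshape(B_, C_, H // 2, 2, W // 2, 2).sum(axis=(3, 5))
                x._accum(g)

            out._backward = bwd
        return out
    if mode != "bilinear":
        raise ValueError(f"unknown upsample mode: {mode!r}")
    # Output pixel (i,j) samples source coordinate ((i+0.5)/2-0.5); with edge
    # clamping this is a weighted blend of at most 4 neighbours with weights
    # 0.75/0.25 along each axis.
    w = _bilinear2x_matrix(x.data.shape[-2])
    w2 = w if x.data.shape[-1] == x.data.shape[-2] else _bilinear2x_matrix(
        x.data.shape[-1]
    )
    y = np.einsum("ih,bchw,jw->bcij", w, x.data, w2, optimize=True)
    out = _make(y, (x,))
    if out._parents:

        def bwd():
            g = np.einsum("ih,bcij,jw->bchw", w, out.grad, w2, optimize=True)
            x._accum(g.astype(np.float32))

        out._backward = bwd
    return out


def _bilinear2x_matrix(n: int) -> np.ndarray:
    """(2n, n) interpolation matrix for exact 2x bilinear upsampling."""
    w = np.zeros((2 * n, n), dtype=np.float32)
    for i in range(2 * n):
        src = (i + 0.5) / 2.0 - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n - 1)
        hi_c = min(max(lo + 1, 0), n - 1)
        w[i, lo_c] += 1.0 - frac
        w[i, hi_c] += frac
    return w


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) via im2col.

    x: (B, Cin, H, W); w: (Cout, Cin, kh, kw); b: (Cout,) or None.
    """
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    B_, Cin, H, W = x.data.shape
    Cout, Cin_w, kh, kw = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"conv2d channel mismatch: input {Cin}, weight {Cin_w}")
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    Ho = (xp.shape[2] - kh) // stride + 1
    Wo = (xp.shape[3] - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B, Cin, Ho, Wo, kh, kw)
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B_ * Ho * Wo, Cin * kh * kw
    )
    wmat = w.data.reshape(Cout, -1)
    y = col @ wmat.T
    if b is not None:
        y = y + b.data
    y = y.reshape(B_, Ho, Wo, Cout).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)
    out = _make(np.ascontiguousarray(y), parents)
    if out._parents:

        def bwd():
            g = out.grad.transpose(0, 2, 3, 1).reshape(B_ * Ho * Wo, Cout)
            if b is not None and (b.requires_grad or b._parents):
                b._accum(g.sum(axis=0))
            if w.requires_grad or w._parents:
                w._accum((g.T @ col).reshape(w.data.shape))
            if x.requires_grad or x._parents:
                gcol = (g @ wmat).reshape(B_, Ho, Wo, Cin, kh, kw)
                gx = np.zeros_like(xp)
                for di in range(kh):
                    for dj in range(kw):
                        gx[
                            :,
                            :,
                            di : di + Ho * stride : stride,
                            dj : dj + Wo * stride : stride,
                        ] += gcol[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
                if padding:
                    gx = gx[:, :, padding : padding + H, padding : padding + W]
                x._accum(gx)

        out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# fused losses
# ---------------------------------------------------------------------------

def smooth_l1(x) -> Tensor:
    """Piecewise box-regression penalty: 0.5 x^2 for |x| < 1, |x| - 0.5 beyond.

    Continuous, once-differentiable at |x| = 1, with gradient clipped to
    [-1, 1] — the insensitivity to outliers that motivates its use for
    bounding-box regression.  Accepts scalars or arrays; elementwise.
    """
    x = as_tensor(x)
    a = np.abs(x.data)
    y = np.where(a < 1.0, 0.5 * x.data * x.data, a - 0.5)
    return _unary(x, y.astype(np.float32), lambda: np.clip(x.data, -1.0, 1.0))


def softmax_cross_entropy(logits, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; labels are integer class indices."""
    logits = as_tensor(logits)
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1))
    n = labels.shape[0]
    nll = lse - z[np.arange(n), labels]
    out = _make(np.float32(nll.mean()), (logits,))
    if out._parents:

        def bwd():
            p = np.exp(z - lse[:, None])
            p[np.arange(n), labels] -= 1.0
            logits._accum(out.grad * p / n)

        out._backward = bwd
    return out


def binary_cross_entropy_with_logits(logits, targets, weights=None) -> Tensor:
    """Weighted sum of elementwise BCE computed stably from logits.

    loss_ij = max(z,0) - z*t + log(1 + exp(-|z|)); the result is
    sum(weights * loss) (weights default to 1, i.e. a plain sum).
    """
    logits = as_tensor(logits)
    t = np.asarray(targets, dtype=np.float32)
    z = logits.data
    loss = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    w = np.float32(1.0) if weights is None else np.asarray(weights, dtype=np.float32)
    out = _make(np.float32((loss * w).sum()), (logits,))
    if out._parents:
        out._backward = lambda: logits._accum(out.grad * w * (_sigmoid_np(z) - t))
    return out
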