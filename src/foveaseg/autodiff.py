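"""Reverse-mode automatic differentiation over NumPy arrays.

The package's network layers, pooling operators and losses are all built from
the :class:`Tensor` primitives defined here.  The design is deliberately small:
a ``Tensor`` wraps an ``ndarray``, every operation records a backward closure,
and :meth:`Tensor.backward` walks the graph in reverse topological order.
Heavy spatial kernels (convolution, sliding-window pooling) are implemented as
single fused primitives with hand-written adjoints; everything else is
composed from elementwise/reduction primitives.  All adjoints are covered by
finite-difference checks in the test suite.
"""

from __future__ import annotations

import contextlib
from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage, signal
from scipy.special import expit

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "solve",
    "conv2d",
    "depthwise_conv2d",
    "bilinear_resize",
    "pad_reflect2d",
    "psa_gather",
    "adaptive_pool",
    "gradcheck",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # make ndarray defer to Tensor in mixed ops

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64 if np.asarray(data).dtype == np.float64 else np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an argument needs a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- graph helper -----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


# -- elementwise / arithmetic ---------------------------------------------


def _binary(a, b, fwd, bwd_a, bwd_b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = fwd(a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(bwd_a(g, a.data, b.data, data), a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(bwd_b(g, a.data, b.data, data), b.data.shape))

    return Tensor._make(data, (a, b), backward)


def add(a, b):
    return _binary(a, b, lambda x, y: x + y, lambda g, x, y, o: g, lambda g, x, y, o: g)


def sub(a, b):
    return _binary(a, b, lambda x, y: x - y, lambda g, x, y, o: g, lambda g, x, y, o: -g)


def mul(a, b):
    return _binary(a, b, lambda x, y: x * y, lambda g, x, y, o: g * y, lambda g, x, y, o: g * x)


def div(a, b):
    return _binary(
        a, b, lambda x, y: x / y, lambda g, x, y, o: g / y, lambda g, x, y, o: -g * x / (y * y)
    )


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    return Tensor._make(data, (a, b), backward)


def _unary(a, fwd, bwd):
    a = _as_tensor(a)
    data = fwd(a.data)

    def backward(g):
        a._accum(bwd(g, a.data, data))

    return Tensor._make(data, (a,), backward)


def neg(a):
    return _unary(a, lambda x: -x, lambda g, x, o: -g)


def exp(a):
    return _unary(a, np.exp, lambda g, x, o: g * o)


def log(a):
    return _unary(a, np.log, lambda g, x, o: g / x)


def sqrt(a):
    return _unary(a, np.sqrt, lambda g, x, o: g * 0.5 / o)


def absolute(a):
    return _unary(a, np.abs, lambda g, x, o: g * np.sign(x))


def power(a, p: float):
    """Elementwise a**p for a scalar exponent."""
    return _unary(a, lambda x: x**p, lambda g, x, o: g * p * x ** (p - 1))


def sigmoid(a):
    return _unary(a, expit, lambda g, x, o: g * o * (1.0 - o))


def relu(a):
    return _unary(a, lambda x: np.maximum(x, 0.0), lambda g, x, o: g * (x > 0))


def clip(a, lo: float, hi: float):
    """Clamp with pass-through gradient strictly inside [lo, hi]."""
    return _unary(
        a,
        lambda x: np.clip(x, lo, hi),
        lambda g, x, o: g * ((x >= lo) & (x <= hi)),
    )


def maximum(a, b):
    return _binary(
        a,
        b,
        np.maximum,
        lambda g, x, y, o: g * (x >= y),
        lambda g, x, y, o: g * (y > x),
    )


# -- reductions / shape ----------------------------------------------------


def tsum(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.data.shape).copy())

    return Tensor._make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod([a.data.shape[i] for i in np.atleast_1d(axis)])
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def _extreme(a, axis, keepdims, fn):
    a = _as_tensor(a)
    data = fn(a.data, axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        d = data
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
            d = np.expand_dims(d, axis)
        mask = a.data == d
        cnt = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
        a._accum(mask * g / cnt)  # ties share the gradient equally

    return Tensor._make(data, (a,), backward)


def tmax(a, axis=None, keepdims=False):
    return _extreme(a, axis, keepdims, np.max)


def tmin(a, axis=None, keepdims=False):
    return _extreme(a, axis, keepdims, np.min)


def reshape(a, shape):
    a = _as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        a._accum(g.reshape(a.data.shape))

    return Tensor._make(data, (a,), backward)


def transpose(a, axes):
    a = _as_tensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        a._accum(g.transpose(inv))

    return Tensor._make(data, (a,), backward)


def concat(tensors, axis=0):
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._make(data, tuple(tensors), backward)


def _has_array_index(idx) -> bool:
    items = idx if isinstance(idx, tuple) else (idx,)
    return any(isinstance(i, np.ndarray) for i in items)


def getitem(a, idx):
    a = _as_tensor(a)
    data = a.data[idx]

    def backward(g):
        ga = np.zeros_like(a.data)
        if _has_array_index(idx):
            np.add.at(ga, idx, g)  # advanced indices may repeat
        else:
            ga[idx] += g
        a._accum(ga)

    return Tensor._make(data, (a,), backward)


# -- linear algebra ---------------------------------------------------------


def solve(A, B):
    """X = A^{-1} B with adjoints gB = A^{-T} gX, gA = -gB X^T (batched OK)."""
    A, B = _as_tensor(A), _as_tensor(B)
    X = np.linalg.solve(A.data, B.data)

    def backward(g):
        gB = np.linalg.solve(np.swapaxes(A.data, -1, -2), g)
        if B.requires_grad:
            B._accum(_unbroadcast(gB, B.data.shape))
        if A.requires_grad:
            gA = -gB @ np.swapaxes(X, -1, -2)
            A._accum(_unbroadcast(gA, A.data.shape))

    return Tensor._make(X, (A, B), backward)


# -- spatial primitives -----------------------------------------------------


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0):
    """2-D cross-correlation, NCHW input, OIHW weight, zero padding.

    Lowered to a single GEMM via im2col; the adjoint reuses the column buffer
    and scatters back through the kernel-offset loop.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    parents = [x, w]
    if b is not None:
        b = _as_tensor(b)
        parents.append(b)
    N, Cin, H, W = x.data.shape
    Cout, Cin2, kh, kw = w.data.shape
    if Cin != Cin2:
        raise ValueError(f"conv2d: input has {Cin} channels, weight expects {Cin2}")
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    wmat = w.data.reshape(Cout, Cin * kh * kw)
    if kh == 1 and kw == 1 and stride == 1:
        cols = xp.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, Cin)
    else:
        view = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
        cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
            N * Ho * Wo, Cin * kh * kw
        )
    out = (cols @ wmat.T).reshape(N, Ho, Wo, Cout).transpose(0, 3, 1, 2)
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, Cout)
        if w.requires_grad:
            w._accum((g2.T @ cols).reshape(w.data.shape))
        if x.requires_grad:
            dcols = g2 @ wmat  # (N*Ho*Wo, Cin*kh*kw)
            if kh == 1 and kw == 1 and stride == 1:
                gxp = dcols.reshape(N, Ho, Wo, Cin).transpose(0, 3, 1, 2)
            else:
                dcols = dcols.reshape(N, Ho, Wo, Cin, kh, kw)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[
                            :, :, i : i + Ho * stride : stride, j : j + Wo * stride : stride
                        ] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                gxp = gxp[:, :, padding : Hp - padding, padding : Wp - padding]
            x._accum(np.ascontiguousarray(gxp))

    return Tensor._make(out, tuple(parents), backward)


def batch_norm_train(x, w, b, eps: float = 1e-5):
    """Fused training-mode batch normalization over axes (0, 2, 3).

    Returns (out, batch_mean, batch_var) with the usual biased variance; the
    adjoint is the closed-form batch-norm gradient.
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    N, C, H, W = x.data.shape
    M = N * H * W
    mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * w.data[None, :, None, None] + b.data[None, :, None, None]

    def backward(g):
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accum((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxhat = g * w.data[None, :, None, None]
            s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            x._accum(inv * (dxhat - s1 / M - xhat * s2 / M))

    t = Tensor._make(out, (x, w, b), backward)
    return t, mu.reshape(C), var.reshape(C)


def depthwise_conv2d(x, w, b=None, padding: int = 0):
    """Per-channel (depthwise) 2-D cross-correlation, stride 1."""
    x, w = _as_tensor(x), _as_tensor(w)
    parents = [x, w]
    if b is not None:
        b = _as_tensor(b)
        parents.append(b)
    N, C, H, W = x.data.shape
    C2, kh, kw = w.data.shape
    if C != C2:
        raise ValueError("depthwise_conv2d: channel mismatch")
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    Ho, Wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    out = np.zeros((N, C, Ho, Wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            out += w.data[None, :, i, j, None, None] * xp[:, :, i : i + Ho, j : j + Wo]
    if b is not None:
        out += b.data[None, :, None, None]

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        gxp = np.zeros_like(xp) if x.requires_grad else None
        gw = np.zeros_like(w.data) if w.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                sl = xp[:, :, i : i + Ho, j : j + Wo]
                if gw is not None:
                    gw[:, i, j] = (g * sl).sum(axis=(0, 2, 3))
                if gxp is not None:
                    gxp[:, :, i : i + Ho, j : j + Wo] += g * w.data[None, :, i, j, None, None]
        if gw is not None:
            w._accum(gw)
        if gxp is not None:
            if padding:
                gxp = gxp[:, :, padding : xp.shape[2] - padding, padding : xp.shape[3] - padding]
            x._accum(gxp)

    return Tensor._make(out, tuple(parents), backward)


@lru_cache(maxsize=128)
def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (half-pixel convention)."""
    A = np.zeros((n_out, n_in))
    if n_in == 1:
        A[:, 0] = 1.0
        return A
    for o in range(n_out):
        src = (o + 0.5) * n_in / n_out - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        f = src - i0
        A[o, i0] += 1.0 - f
        A[o, i1] += f
    return A


def _separable_resize(x, A, B):
    data = np.einsum("oh,nchw,pw->ncop", A, x.data, B, optimize=True)

    def backward(g):
        x._accum(np.einsum("oh,ncop,pw->nchw", A, g, B, optimize=True))

    return Tensor._make(data, (x,), backward)


def bilinear_resize(x, out_h: int, out_w: int):
    """Bilinear spatial resize of an NCHW tensor (separable matrix form)."""
    x = _as_tensor(x)
    N, C, H, W = x.data.shape
    if (H, W) == (out_h, out_w):
        return x
    A = _resize_matrix(H, out_h).astype(x.data.dtype)
    B = _resize_matrix(W, out_w).astype(x.data.dtype)
    return _separable_resize(x, A, B)


@lru_cache(maxsize=128)
def _box_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D block-average (adaptive average pooling) matrix."""
    A = np.zeros((n_out, n_in))
    bounds = np.linspace(0, n_in, n_out + 1).round().astype(int)
    for o in range(n_out):
        lo, hi = bounds[o], max(bounds[o + 1], bounds[o] + 1)
        A[o, lo:hi] = 1.0 / (hi - lo)
    return A


def box_resize(x, out_h: int, out_w: int):
    """Adaptive average pooling of an NCHW tensor to a fixed output size."""
    x = _as_tensor(x)
    N, C, H, W = x.data.shape
    if (H, W) == (out_h, out_w):
        return x
    A = _box_matrix(H, out_h).astype(x.data.dtype)
    B = _box_matrix(W, out_w).astype(x.data.dtype)
    return _separable_resize(x, A, B)


@lru_cache(maxsize=128)
def _reflect_index(n: int, p: int) -> np.ndarray:
    """Index map of a reflect (mirror, edge not repeated) pad of width p."""
    if n == 1:
        return np.zeros(1 + 2 * p, dtype=int)
    idx = np.arange(-p, n + p)
    period = 2 * (n - 1)
    return (n - 1) - np.abs((n - 1) - np.mod(idx, period))


def _fold_reflect(gpad: np.ndarray, p: int) -> np.ndarray:
    """Adjoint of reflect padding on the last two axes."""
    if p == 0:
        return gpad
    N, C, Hp, Wp = gpad.shape
    H, W = Hp - 2 * p, Wp - 2 * p
    ih = _reflect_index(H, p)
    iw = _reflect_index(W, p)
    tmp = np.zeros((N, C, H, Wp), dtype=gpad.dtype)
    np.add.at(tmp.transpose(2, 0, 1, 3), ih, gpad.transpose(2, 0, 1, 3))
    out = np.zeros((N, C, H, W), dtype=gpad.dtype)
    np.add.at(out.transpose(3, 0, 1, 2), iw, tmp.transpose(3, 0, 1, 2))
    return out


def pad_reflect2d(x, p: int):
    """Reflect (mirror-without-edge) pad of the last two axes."""
    x = _as_tensor(x)
    if p == 0:
        return x
    data = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), mode="reflect")

    def backward(g):
        x._accum(_fold_reflect(g, p))

    return Tensor._make(data, (x,), backward)


def psa_gather(h, idx: np.ndarray):
    """Gather pointwise attention from an over-complete embedding.

    ``h`` has shape (N, C2, L) — one C2-channel embedding per spatial position
    (L = H*W flattened) — and ``idx`` has shape (L, L) with ``idx[p, q]`` the
    embedding channel encoding the relative offset of source position q seen
    from target position p.  Returns (N, L, L) with ``out[n, p, q] =
    h[n, idx[p, q], p]``.
    """
    h = _as_tensor(h)
    N, C2, L = h.data.shape
    ht = np.ascontiguousarray(h.data.transpose(0, 2, 1))  # (N, L, C2)
    out = np.take_along_axis(ht, idx[None, :, :], axis=2)

    def backward(g):
        ght = np.zeros((N, L * C2), dtype=h.data.dtype)
        flat = (np.arange(L)[:, None] * C2 + idx).ravel()
        for n in range(N):
            np.add.at(ght[n], flat, g[n].ravel())
        h._accum(ght.reshape(N, L, C2).transpose(0, 2, 1))

    return Tensor._make(out, (h,), backward)


def _spread_full(g: np.ndarray, w: int) -> np.ndarray:
    """Sum each entry of g over a w-by-w window: full correlation with ones."""
    kernel = np.ones((1, 1, w, w), dtype=np.float64)
    return signal.fftconvolve(g.astype(np.float64), kernel, mode="full", axes=(2, 3))


def adaptive_pool(x, radii: np.ndarray, method: str = "average", p: float = 2.0, mix: float = 0.5):
    """Stride-1 pooling with a per-position radius map.

    At position i the window is the square of side (2*r_i - 1) centred on i,
    with mirror (reflect) padding at the borders.  ``radii`` is an integer
    (H, W) array and is treated as data, not as part of the autodiff graph:
    the floor in the radius law is piecewise constant, so no gradient flows
    through the radii.  Methods:

    - ``average``: window mean,
    - ``lp``: (mean |x|^p)^(1/p),
    - ``mixed``: mix*max + (1-mix)*mean,
    - ``identity``: passthrough.
    """
    x = _as_tensor(x)
    if method == "identity":
        return x
    if method not in ("average", "lp", "mixed"):
        raise ValueError(f"unknown pooling method: {method}")
    radii = np.asarray(radii)
    N, C, H, W = x.data.shape
    if radii.shape == (H, W):
        radii = np.broadcast_to(radii, (N, H, W))
    if radii.shape != (N, H, W):
        raise ValueError("radius map must be (H, W) or (N, H, W) matching the feature map")
    if radii.min() < 1:
        raise ValueError("pooling radii must be >= 1")
    xd = x.data.astype(np.float64)
    out = np.empty_like(xd)
    uniq = np.unique(radii)
    masks = {int(r): radii == r for r in uniq}  # (N, H, W) boolean
    for r in uniq:
        r = int(r)
        wsz = 2 * r - 1
        m = masks[r]
        if wsz == 1:
            # a 1x1 window is the identity, except lp which yields |x|
            f = np.abs(xd) if method == "lp" else xd
        elif method == "average":
            f = ndimage.uniform_filter(xd, size=(1, 1, wsz, wsz), mode="mirror")
        elif method == "lp":
            mp = ndimage.uniform_filter(np.abs(xd) ** p, size=(1, 1, wsz, wsz), mode="mirror")
            f = mp ** (1.0 / p)
        else:  # mixed
            mx = ndimage.maximum_filter(xd, size=(1, 1, wsz, wsz), mode="mirror")
            av = ndimage.uniform_filter(xd, size=(1, 1, wsz, wsz), mode="mirror")
            f = mix * mx + (1.0 - mix) * av
        out = np.where(m[:, None, :, :], f, out)

    def backward(g):
        gx = np.zeros((N, C, H, W), dtype=np.float64)
        g = g.astype(np.float64)
        for r in uniq:
            r = int(r)
            wsz = 2 * r - 1
            n = float(wsz * wsz)
            m = masks[r]
            gm = np.where(m[:, None, :, :], g, 0.0)
            pad = r - 1
            if method == "average":
                t = _spread_full(gm / n, wsz)
                gx += _fold_reflect(t, pad) if pad else t
            elif method == "lp":
                mp = (
                    ndimage.uniform_filter(np.abs(xd) ** p, size=(1, 1, wsz, wsz), mode="mirror")
                    if wsz > 1
                    else np.abs(xd) ** p
                )
                coef = np.zeros_like(mp)
                nz = mp > 0
                coef[nz] = mp[nz] ** ((1.0 - p) / p)
                t = _spread_full(gm * coef / n, wsz)
                xp_pad = (
                    np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="reflect")
                    if pad
                    else xd
                )
                t *= np.abs(xp_pad) ** (p - 1.0) * np.sign(xp_pad)
                gx += _fold_reflect(t, pad) if pad else t
            else:  # mixed
                t = _spread_full(gm * (1.0 - mix) / n, wsz)
                xp_pad = (
                    np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="reflect")
                    if pad
                    else xd
                )
                Hp, Wp = xp_pad.shape[2], xp_pad.shape[3]
                win = sliding_window_view(xp_pad, (wsz, wsz), axis=(2, 3)).reshape(N, C, H, W, -1)
                am = win.argmax(axis=-1)
                ai, aj = np.unravel_index(am, (wsz, wsz))
                base_i = np.arange(H)[:, None] + ai  # window start == output index
                base_j = np.arange(W)[None, :] + aj
                flat = (
                    np.arange(N)[:, None, None, None] * (C * Hp * Wp)
                    + np.arange(C)[None, :, None, None] * (Hp * Wp)
                    + base_i * Wp
                    + base_j
                )
                np.add.at(t.reshape(-1), flat.ravel(), (gm * mix).ravel())
                gx += _fold_reflect(t, pad) if pad else t
        x._accum(gx.astype(x.data.dtype))

    return Tensor._make(out.astype(x.data.dtype), (x,), backward)


# -- numerical gradient check ----------------------------------------------


def gradcheck(fn, inputs, eps: float = 1e-5, atol: float = 1e-4, rtol: float = 1e-3) -> bool:
    """Compare analytic gradients of scalar-valued fn against central differences.

    ``inputs`` are float64 Tensors with requires_grad=True; returns True when
    every coordinate agrees within atol + rtol*|fd|.
    """
    out = fn(*inputs)
    for t in inputs:
        t.grad = None
    out.backward()
    ok = True
    for t in inputs:
        ana = t.grad if t.grad is not None else np.zeros_like(t.data)
        flat = t.data.ravel()
        fd = np.zeros_like(flat)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn(*inputs).item()
            flat[i] = orig - eps
            lo = fn(*inputs).item()
            flat[i] = orig
            fd[i] = (hi - lo) / (2 * eps)
        fd = fd.reshape(t.data.shape)
        if not np.allclose(ana, fd, atol=atol, rtol=rtol):
            ok = False
    return ok


# Tensor operator sugar -----------------------------------------------------

Tensor.__add__ = lambda self, o: add(self, o)
Tensor.__radd__ = lambda self, o: add(o, self)
Tensor.__sub__ = lambda self, o: sub(self, o)
Tensor.__rsub__ = lambda self, o: sub(o, self)
Tensor.__mul__ = lambda self, o: mul(self, o)
Tensor.__rmul__ = lambda self, o: mul(o, self)
Tensor.__truediv__ = lambda self, o: div(self, o)
Tensor.__rtruediv__ = lambda self, o: div(o, self)
Tensor.__neg__ = lambda self: neg(self)
Tensor.__matmul__ = lambda self, o: matmul(self, o)
Tensor.__pow__ = lambda self, p: power(self, p)
Tensor.__getitem__ = lambda self, idx: getitem(self, idx)
Tensor.sum = tsum
Tensor.mean = tmean
Tensor.max = tmax
Tensor.min = tmin
Tensor.reshape = lambda self, *s: reshape(self, s if len(s) > 1 else s[0])
Tensor.transpose = lambda self, *axes: transpose(self, axes)
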