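"""Compact reverse-mode automatic differentiation over numpy arrays.

The engine exists so the adversarial training objective — in particular the
gradient penalty, which regularises the norm of the critic's *input* gradient
and therefore needs derivatives *of* derivatives — can be optimised with plain
numpy. It is a classic tape-based design: every primitive records its parents
together with a vector-Jacobian-product (VJP) closure, and :func:`grad`
replays the tape in reverse topological order. VJP closures are themselves
written in terms of primitives, so calling :func:`grad` with
``create_graph=True`` yields gradients that carry their own tape and can be
differentiated again (double backprop).

Only the operations the networks in this package need are implemented:
elementwise arithmetic, matmul, reductions, the usual activations, shape
surgery, and the im2col/col2im pair that convolution layers are built from.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "grad",
    "no_grad",
    "concat",
    "maximum_axis",
    "im2col",
    "col2im",
    "pad_zero_hw",
    "crop_hw",
    "take_hw",
    "reflect_pad_hw",
]

# Global switch: while False, primitives do not record parents (used both by
# the no_grad context and internally when replaying a tape without
# create_graph).
_GRAPH_ENABLED = [True]

# Default element type for newly created tensors. float64 keeps analytic
# checks exact; training switches to float32 for throughput (see use_dtype).
_DEFAULT_DTYPE = [np.float64]


class use_dtype:
    """Context manager setting the element type of newly created tensors."""

    def __init__(self, dtype):
        self.dtype = np.dtype(dtype)

    def __enter__(self):
        self._prev = _DEFAULT_DTYPE[0]
        _DEFAULT_DTYPE[0] = self.dtype
        return self

    def __exit__(self, *exc):
        _DEFAULT_DTYPE[0] = self._prev
        return False


class no_grad:
    """Context manager disabling tape recording."""

    def __enter__(self):
        self._prev = _GRAPH_ENABLED[0]
        _GRAPH_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAPH_ENABLED[0] = self._prev
        return False


class Tensor:
    """A numpy array plus the tape metadata needed for reverse-mode AD."""

    __slots__ = ("data", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE[0])
        self.requires_grad = bool(requires_grad)
        self._parents = _parents  # tuple of (Tensor, vjp_fn)

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator overloads ----------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis, keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents) -> Tensor:
    """Build an op result, recording parents only while the tape is on."""
    if _GRAPH_ENABLED[0]:
        kept = tuple((p, fn) for p, fn in parents if p.requires_grad)
        if kept:
            return Tensor(data, requires_grad=True, _parents=kept)
    return Tensor(data)


def _sum_to_shape(g: Tensor, shape) -> Tensor:
    """Reverse numpy broadcasting: reduce g down to `shape`."""
    if g.shape == tuple(shape):
        return g
    # sum away leading broadcast axes
    extra = g.ndim - len(shape)
    if extra > 0:
        g = sum_(g, axis=tuple(range(extra)), keepdims=False)
    axes = tuple(i for i, d in enumerate(shape) if d == 1 and g.shape[i] != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    return reshape(g, tuple(shape))


# ---------------------------------------------------------------------------
# arithmetic primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data
    return _make(out, (
        (a, lambda g: _sum_to_shape(g, a.shape)),
        (b, lambda g: _sum_to_shape(g, b.shape)),
    ))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data
    return _make(out, (
        (a, lambda g: _sum_to_shape(mul(g, b), a.shape)),
        (b, lambda g: _sum_to_shape(mul(g, a), b.shape)),
    ))


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data / b.data
    return _make(out, (
        (a, lambda g: _sum_to_shape(div(g, b), a.shape)),
        (b, lambda g: _sum_to_shape(mul(g, div(-a, mul(b, b))), b.shape)),
    ))


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    p = float(p)
    out = a.data ** p
    return _make(out, (
        (a, lambda g: mul(g, mul(p, power(a, p - 1.0)))),
    ))


def sqrt(a) -> Tensor:
    # expressed through power() so second derivatives stay exact
    return power(a, 0.5)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)
    cell = []
    t = _make(out, ((a, lambda g: mul(g, cell[0])),))
    cell.append(t if t.requires_grad else Tensor(out))
    return t


def log(a) -> Tensor:
    a = as_tensor(a)
    return _make(np.log(a.data), ((a, lambda g: div(g, a)),))


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data

    def _swap(t: Tensor) -> Tensor:
        axes = list(range(t.ndim))
        axes[-1], axes[-2] = axes[-2], axes[-1]
        return transpose(t, tuple(axes))

    return _make(out, (
        (a, lambda g: _sum_to_shape(matmul(g, _swap(b)), a.shape)),
        (b, lambda g: _sum_to_shape(matmul(_swap(a), g), b.shape)),
    ))


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g: Tensor) -> Tensor:
        gd = g
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            shape = list(a.shape)
            for i in sorted(ax):
                shape[i if i >= 0 else a.ndim + i] = 1
            gd = reshape(gd, tuple(shape))
        elif axis is None and not keepdims:
            gd = reshape(gd, (1,) * a.ndim)
        return broadcast_to(gd, a.shape)

    return _make(out, ((a, vjp),))


def mean_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = 1
        for i in ax:
            n *= a.shape[i]
    return mul(sum_(a, axis, keepdims), 1.0 / n)


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    out = np.broadcast_to(a.data, shape)  # read-only view; data is never mutated
    return _make(out, ((a, lambda g: _sum_to_shape(g, a.shape)),))


def maximum_axis(a, axis, keepdims: bool = False) -> Tensor:
    """Max-reduction; ties share the incoming gradient equally."""
    a = as_tensor(a)
    out = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == out).astype(np.float64)
    mask /= mask.sum(axis=axis, keepdims=True)
    mask_t = Tensor(mask)
    res = out if keepdims else np.squeeze(out, axis=axis)

    def vjp(g: Tensor) -> Tensor:
        gd = g
        if not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            shape = list(a.shape)
            for i in sorted(ax):
                shape[i if i >= 0 else a.ndim + i] = 1
            gd = reshape(gd, tuple(shape))
        return mul(broadcast_to(gd, a.shape), mask_t)

    return _make(res, ((a, vjp),))


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = Tensor((a.data > 0).astype(np.float64))
    return _make(a.data * mask.data, ((a, lambda g: mul(g, mask)),))


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    factor = np.where(a.data > 0, 1.0, slope)
    factor_t = Tensor(factor)
    return _make(a.data * factor, ((a, lambda g: mul(g, factor_t)),))


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    y = 1.0 / (1.0 + np.exp(-a.data))
    cell = []
    t = _make(y, ((a, lambda g: mul(g, mul(cell[0], 1.0 - cell[0]))),))
    cell.append(t if t.requires_grad else Tensor(y))
    return t


def tanh(a) -> Tensor:
    a = as_tensor(a)
    y = np.tanh(a.data)
    cell = []
    t = _make(y, ((a, lambda g: mul(g, 1.0 - mul(cell[0], cell[0]))),))
    cell.append(t if t.requires_grad else Tensor(y))
    return t


# ---------------------------------------------------------------------------
# shape surgery
# ---------------------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    return _make(a.data.reshape(shape), ((a, lambda g: reshape(g, a.shape)),))


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    inv = tuple(np.argsort(axes))
    return _make(a.data.transpose(axes), ((a, lambda g: transpose(g, inv)),))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    parents = []
    start = 0
    for t in tensors:
        width = t.shape[axis]
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(start, start + width)
        parents.append((t, (lambda s: (lambda g: getitem(g, tuple(s))))(list(sl))))
        start += width
    return _make(out, tuple(parents))


def getitem(a, idx) -> Tensor:
    """Basic (slice-only) indexing; VJP pads the gradient back with zeros."""
    a = as_tensor(a)
    out = a.data[idx]

    def vjp(g: Tensor) -> Tensor:
        buf = np.zeros(a.shape)
        buf[idx] = g.data
        if _GRAPH_ENABLED[0] and g.requires_grad:
            # re-express as primitives so double backprop can pass through
            return scatter_into(g, a.shape, idx)
        return Tensor(buf)

    return _make(out, ((a, vjp),))


def scatter_into(g, shape, idx) -> Tensor:
    g = as_tensor(g)
    buf = np.zeros(shape)
    buf[idx] = g.data
    return _make(buf, ((g, lambda gg: getitem(gg, idx)),))


# ---------------------------------------------------------------------------
# image-specific linear operators
# ---------------------------------------------------------------------------

def pad_zero_hw(a, p: int) -> Tensor:
    """Zero-pad the trailing two (spatial) axes of an NCHW tensor by p."""
    a = as_tensor(a)
    if p == 0:
        return a
    out = np.pad(a.data, ((0, 0), (0, 0), (p, p), (p, p)))
    sl = (slice(None), slice(None), slice(p, -p), slice(p, -p))
    return _make(out, ((a, lambda g: getitem(g, sl)),))


def crop_hw(a, r0: int, r1: int, c0: int, c1: int) -> Tensor:
    return getitem(a, (slice(None), slice(None), slice(r0, r1), slice(c0, c1)))


def take_hw(a, row_idx: np.ndarray, col_idx: np.ndarray) -> Tensor:
    """Gather rows/cols of the spatial axes; adjoint is scatter-add."""
    a = as_tensor(a)
    out = a.data[:, :, row_idx[:, None], col_idx[None, :]]
    H, W = a.shape[2], a.shape[3]

    def vjp(g: Tensor) -> Tensor:
        return scatter_add_hw(g, row_idx, col_idx, H, W)

    return _make(out, ((a, vjp),))


def scatter_add_hw(g, row_idx: np.ndarray, col_idx: np.ndarray, H: int, W: int) -> Tensor:
    g = as_tensor(g)
    # adjoint of the separable gather: Rᵀ · g · C with one-hot selectors
    dt = g.data.dtype
    R = np.zeros((len(row_idx), H), dtype=dt)
    R[np.arange(len(row_idx)), row_idx] = 1.0
    C = np.zeros((len(col_idx), W), dtype=dt)
    C[np.arange(len(col_idx)), col_idx] = 1.0
    buf = np.matmul(R.T, np.matmul(g.data, C))
    return _make(buf, ((g, lambda gg: take_hw(gg, row_idx, col_idx)),))


def _reflect_index(n: int, p: int) -> np.ndarray:
    # numpy 'reflect' convention: edge sample not repeated
    return np.concatenate([np.arange(p, 0, -1), np.arange(n), np.arange(n - 2, n - 2 - p, -1)])


def reflect_pad_hw(a, p: int) -> Tensor:
    a = as_tensor(a)
    if p == 0:
        return a
    ri = _reflect_index(a.shape[2], p)
    ci = _reflect_index(a.shape[3], p)
    return take_hw(a, ri, ci)


def im2col(a, k: int, stride: int) -> Tensor:
    """Unfold an (N,C,H,W) tensor into (C*k*k, N*L) sliding-window columns.

    The column-major-in-batch layout lets a convolution be a single GEMM
    against a (out_ch, C*k*k) weight matrix.
    """
    a = as_tensor(a)
    N, C, H, W = a.shape
    Ho = (H - k) // stride + 1
    Wo = (W - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(a.data, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]            # (N,C,Ho,Wo,k,k)
    cols = np.ascontiguousarray(win.transpose(1, 4, 5, 0, 2, 3)) \
        .reshape(C * k * k, N * Ho * Wo)

    def vjp(g: Tensor) -> Tensor:
        return col2im(g, (H, W), k, stride, C, N)

    return _make(cols, ((a, vjp),))


def col2im(cols, hw, k: int, stride: int, C: int, N: int) -> Tensor:
    """Adjoint of :func:`im2col`: overlap-add columns back onto the image grid."""
    cols = as_tensor(cols)
    H, W = hw
    Ho = (H - k) // stride + 1
    Wo = (W - k) // stride + 1
    blocks = cols.data.reshape(C, k, k, N, Ho, Wo)
    out = np.zeros((N, C, H, W), dtype=cols.data.dtype)
    for i in range(k):
        he = i + stride * Ho
        for j in range(k):
            we = j + stride * Wo
            out[:, :, i:he:stride, j:we:stride] += \
                blocks[:, i, j].transpose(1, 0, 2, 3)

    def vjp(g: Tensor) -> Tensor:
        return im2col(g, k, stride)

    return _make(out, ((cols, vjp),))


# ---------------------------------------------------------------------------
# direct stride-1 convolution (no im2col materialisation)
#
# conv2d_s1, convT2d_s1 and convW2d_s1 form a closed adjoint set: every VJP
# of each member is again a member, so arbitrary-order derivatives are exact.
# ---------------------------------------------------------------------------

def _swv(arr: np.ndarray, k: int):
    return np.lib.stride_tricks.sliding_window_view(arr, (k, k), axis=(2, 3))


# Kernels at or above this size run through FFTs (the sliding-window einsum
# duplicates each pixel k^2 times, which dominates for 7x7 kernels).
_FFT_KERNEL_AREA = 25


def _raw_conv(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """out[n,o,h,v] = sum_{c,i,j} x[n,c,h+i,v+j] w[o,c,i,j] (valid corr.)."""
    k = w.shape[2]
    if k * k < _FFT_KERNEL_AREA:
        return np.einsum("nchwij,ocij->nohw", _swv(x, k), w, optimize=True)
    import scipy.fft as sfft
    Hp, Wp = x.shape[2], x.shape[3]
    X = sfft.rfft2(x)
    Wf = sfft.rfft2(w, s=(Hp, Wp))
    Y = np.einsum("nchw,ochw->nohw", X, np.conj(Wf), optimize=True)
    out = sfft.irfft2(Y, s=(Hp, Wp))[:, :, :Hp - k + 1, :Wp - k + 1]
    return np.ascontiguousarray(out)


def _raw_tconv(g: np.ndarray, w: np.ndarray) -> np.ndarray:
    """dx[n,c,p,q] = sum_{o,i,j} g[n,o,p-i,q-j] w[o,c,i,j] (full conv.)."""
    k = w.shape[2]
    if k * k < _FFT_KERNEL_AREA:
        gp = np.pad(g, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
        return np.einsum("nohwij,ocij->nchw", _swv(gp, k),
                         w[:, :, ::-1, ::-1], optimize=True)
    import scipy.fft as sfft
    H = g.shape[2] + k - 1
    W = g.shape[3] + k - 1
    G = sfft.rfft2(g, s=(H, W))
    Wf = sfft.rfft2(w, s=(H, W))
    Y = np.einsum("nohw,ochw->nchw", G, Wf, optimize=True)
    return np.ascontiguousarray(sfft.irfft2(Y, s=(H, W)))


def _raw_wgrad(x: np.ndarray, g: np.ndarray, k: int) -> np.ndarray:
    """dw[o,c,i,j] = sum_{n,h,v} g[n,o,h,v] x[n,c,h+i,v+j]."""
    if k * k < _FFT_KERNEL_AREA:
        win = np.lib.stride_tricks.sliding_window_view(
            x, (g.shape[2], g.shape[3]), axis=(2, 3))
        return np.einsum("ncijhw,nohw->ocij", win, g, optimize=True)
    import scipy.fft as sfft
    Hp, Wp = x.shape[2], x.shape[3]
    X = sfft.rfft2(x)
    G = sfft.rfft2(g, s=(Hp, Wp))
    Y = np.einsum("nchw,nohw->ochw", X, np.conj(G), optimize=True)
    return np.ascontiguousarray(sfft.irfft2(Y, s=(Hp, Wp))[:, :, :k, :k])


def conv2d_s1(x, w) -> Tensor:
    """Valid cross-correlation of (N,C,H,W) with (O,C,k,k), stride 1."""
    x, w = as_tensor(x), as_tensor(w)
    k = w.shape[2]
    out = _raw_conv(x.data, w.data)
    return _make(out, (
        (x, lambda g: convT2d_s1(g, w)),
        (w, lambda g: convW2d_s1(x, g, k)),
    ))


def convT2d_s1(g, w) -> Tensor:
    """Adjoint of conv2d_s1 in its data argument (full convolution)."""
    g, w = as_tensor(g), as_tensor(w)
    k = w.shape[2]
    out = _raw_tconv(g.data, w.data)
    return _make(out, (
        (g, lambda u: conv2d_s1(u, w)),
        (w, lambda u: convW2d_s1(u, g, k)),
    ))


def convW2d_s1(x, g, k: int) -> Tensor:
    """Adjoint of conv2d_s1 in its weight argument."""
    x, g = as_tensor(x), as_tensor(g)
    out = _raw_wgrad(x.data, g.data, k)
    return _make(out, (
        (x, lambda v: convT2d_s1(g, v)),
        (g, lambda v: conv2d_s1(x, v)),
    ))


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def _toposort(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node._parents:
            if id(parent) not in seen:
                stack.append((parent, False))
    return order  # parents before children


def grad(output: Tensor, inputs, create_graph: bool = False, grad_output=None):
    """Gradients of a scalar `output` w.r.t. each tensor in `inputs`.

    With ``create_graph=True`` the returned gradients carry their own tape and
    can be differentiated again — this is what the gradient penalty relies on.
    Inputs unreachable from the output get a zero gradient of matching shape.
    """
    if not isinstance(inputs, (list, tuple)):
        inputs = [inputs]
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    grads = {id(output): as_tensor(grad_output)}
    order = _toposort(output)
    wanted = {id(t) for t in inputs}
    prev = _GRAPH_ENABLED[0]
    _GRAPH_ENABLED[0] = bool(create_graph)
    try:
        for node in reversed(order):
            g = grads.get(id(node))
            if g is None:
                continue
            for parent, vjp in node._parents:
                pg = vjp(g)
                acc = grads.get(id(parent))
                grads[id(parent)] = pg if acc is None else add(acc, pg)
            if id(node) not in wanted:
                del grads[id(node)]
    finally:
        _GRAPH_ENABLED[0] = prev
    return [grads.get(id(t), Tensor(np.zeros(t.shape))) for t in inputs]
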