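"""Reverse-mode automatic differentiation on numpy arrays.

A small define-by-run engine: every operation on :class:`Tensor` records a
closure computing the vector-Jacobian product, and :meth:`Tensor.backward`
replays them in reverse topological order.  Only the operations the
segmentation model needs are provided (elementwise arithmetic, reductions,
2-D convolution via im2col, average pooling, batch normalisation, bilinear
resizing, concatenation).  Arrays keep whatever float dtype they come in
with, so the network can run in float32 while loss checks run in float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "avg_pool2",
    "bilinear_resize",
    "batch_norm",
    "no_grad",
    "is_grad_enabled",
]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def is_grad_enabled() -> bool:
    return _grad_enabled


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    # leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float64)
        if data.dtype.kind != "f":
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction of graph nodes -------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g, self.data.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(g, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(g * self.data, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _sum_to_shape(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    # -- reductions and elementwise functions -----------------------------
    def sum(self):
        def backward(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.data.shape).astype(self.data.dtype))

        return Tensor._make(np.asarray(self.data.sum()), (self,), backward)

    def mean(self):
        n = self.data.size

        def backward(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, g / n))

        return Tensor._make(np.asarray(self.data.mean()), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = expit(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def clamp(self, lo: float, hi: float):
        """Clamp values; gradient passes through unclipped entries only."""
        mask = (self.data > lo) & (self.data < hi)
        data = np.clip(self.data, lo, hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(data, (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accum(full)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- backprop ---------------------------------------------------------
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # the graph is single-use; free intermediates eagerly
                if node is not self:
                    node._backward = None
                    node._parents = ()


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# 2-D convolution (NCHW) via im2col / col2im
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, dilation: int,
            pad: int) -> tuple[np.ndarray, tuple[int, int]]:
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    khe = (kh - 1) * dilation + 1
    kwe = (kw - 1) * dilation + 1
    v = sliding_window_view(x, (khe, kwe), axis=(2, 3))
    v = v[:, :, ::stride, ::stride, ::dilation, ::dilation]
    ho, wo = v.shape[2], v.shape[3]
    cols = np.ascontiguousarray(v.transpose(0, 1, 4, 5, 2, 3)).reshape(
        n, c * kh * kw, ho * wo
    )
    return cols, (ho, wo)


def _col2im(gcols: np.ndarray, x_shape: tuple[int, ...], kh: int, kw: int,
            stride: int, dilation: int, pad: int, ho: int, wo: int) -> np.ndarray:
    n, c, h, w = x_shape
    gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=gcols.dtype)
    g = gcols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        r0 = i * dilation
        r1 = r0 + (ho - 1) * stride + 1
        for j in range(kw):
            c0 = j * dilation
            c1 = c0 + (wo - 1) * stride + 1
            gx[:, :, r0:r1:stride, c0:c1:stride] += g[:, :, i, j]
    if pad:
        gx = gx[:, :, pad:pad + h, pad:pad + w]
    return gx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """Cross-correlation of NCHW input with OIHW weights."""
    cout, cin, kh, kw = weight.data.shape
    if x.data.shape[1] != cin:
        raise ValueError(
            f"conv2d: input has {x.data.shape[1]} channels, weight expects {cin}"
        )
    n = x.data.shape[0]
    cols, (ho, wo) = _im2col(x.data, kh, kw, stride, dilation, padding)
    w2 = weight.data.reshape(cout, cin * kh * kw)
    y = np.matmul(w2, cols)  # (N, Cout, Ho*Wo)
    if bias is not None:
        y += bias.data[None, :, None]
    y = y.reshape(n, cout, ho, wo)

    def backward(g):
        gy = g.reshape(n, cout, ho * wo)
        if bias is not None and bias.requires_grad:
            bias._accum(gy.sum(axis=(0, 2)))
        if weight.requires_grad:
            gw = np.einsum("nol,nkl->ok", gy, cols, optimize=True)
            weight._accum(gw.reshape(weight.data.shape))
        if x.requires_grad:
            gcols = np.matmul(w2.T, gy)
            x._accum(
                _col2im(gcols, x.data.shape, kh, kw, stride, dilation,
                        padding, ho, wo)
            )

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(y, parents, backward)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling with stride 2 (even spatial dims required)."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"avg_pool2 requires even spatial dims, got {h}x{w}")
    y = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
            x._accum(gx.astype(x.data.dtype))

    return Tensor._make(y, (x,), backward)


# ---------------------------------------------------------------------------
# Bilinear resize (half-pixel centers, i.e. align_corners=False)
# ---------------------------------------------------------------------------

_RESIZE_CACHE: dict[tuple[int, int, str], np.ndarray] = {}


def _resize_matrix(n_in: int, n_out: int, dtype: np.dtype) -> np.ndarray:
    key = (n_in, n_out, np.dtype(dtype).str)
    m = _RESIZE_CACHE.get(key)
    if m is not None:
        return m
    m = np.zeros((n_out, n_in), dtype=dtype)
    for o in range(n_out):
        src = (o + 0.5) * n_in / n_out - 0.5
        i0 = int(np.floor(src))
        w1 = src - i0
        i0c = min(max(i0, 0), n_in - 1)
        i1c = min(max(i0 + 1, 0), n_in - 1)
        m[o, i0c] += 1.0 - w1
        m[o, i1c] += w1
    _RESIZE_CACHE[key] = m
    return m


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear interpolation of an NCHW tensor."""
    n, c, h, w = x.data.shape
    mh = _resize_matrix(h, out_h, x.data.dtype)
    mw = _resize_matrix(w, out_w, x.data.dtype)
    tmp = np.einsum("oh,nchw->ncow", mh, x.data, optimize=True)
    y = np.einsum("pw,ncow->ncop", mw, tmp, optimize=True)

    def backward(g):
        if x.requires_grad:
            gt = np.einsum("pw,ncop->ncow", mw, g, optimize=True)
            x._accum(np.einsum("oh,ncow->nchw", mh, gt, optimize=True))

    return Tensor._make(y, (x,), backward)


# ---------------------------------------------------------------------------
# Batch normalisation
# ---------------------------------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray, *,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation with affine transform.

    ``running_mean``/``running_var`` are plain arrays updated in place during
    training and consulted in eval mode.
    """
    g4 = gamma.data[None, :, None, None]
    b4 = beta.data[None, :, None, None]
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
        inv_std = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
        y = g4 * xhat + b4

        def backward(grad):
            if gamma.requires_grad:
                gamma._accum((grad * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accum(grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                dxhat = grad * g4
                m1 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
                m2 = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                x._accum(inv_std[None, :, None, None] * (dxhat - m1 - xhat * m2))

        return Tensor._make(y, (x, gamma, beta), backward)

    inv_std = 1.0 / np.sqrt(running_var + eps)
    scale = (gamma.data * inv_std)[None, :, None, None]
    shift = (beta.data - gamma.data * running_mean * inv_std)[None, :, None, None]
    y = x.data * scale + shift

    def backward(grad):
        if gamma.requires_grad:
            xhat = (x.data - running_mean[None, :, None, None]) * inv_std[None, :, None, None]
            gamma._accum((grad * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accum(grad * scale)

    return Tensor._make(y, (x, gamma, beta), backward)
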