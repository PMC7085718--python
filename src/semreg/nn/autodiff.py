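"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains convolutional registration networks end-to-end through
differentiable warping, B-spline densification and pooling layers.  This
module provides the small tape-based engine those layers are built on:
a :class:`Tensor` wrapping a float32 ``ndarray`` plus the closed set of
operations the networks need (convolution, stride-1 average pooling with
replicate padding, nearest upsampling, bilinear sampling, softmax, and the
usual arithmetic/reductions).

Every operation records a gradient closure; :meth:`Tensor.backward` walks
the tape in reverse topological order.  Gradients are plain ``ndarray``s
accumulated on tensors created with ``requires_grad=True``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "avg_pool_smooth",
    "upsample_nearest",
    "crop",
    "bilinear_sample",
    "softmax",
    "gather_class",
    "leaky_relu",
]


class Tensor:
    """A float32 array node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "_grad_fn", "requires_grad")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.parents: tuple = ()
        self._grad_fn = None
        self.requires_grad = bool(requires_grad)

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple, grad_fn) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.parents = parents
            out._grad_fn = grad_fn
            out.requires_grad = True
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

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every ancestor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (scaling-and-squaring)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))

        self.grad = (
            np.ones_like(self.data)
            if grad is None
            else np.asarray(grad, dtype=np.float32)
        )
        for node in reversed(topo):
            if node._grad_fn is None or node.grad is None:
                continue
            grads = node._grad_fn(node.grad)
            for parent, g in zip(node.parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                g = g.astype(np.float32, copy=False)
                parent.grad = g if parent.grad is None else parent.grad + g
            if node is not self:
                node.grad = None  # free intermediate buffers eagerly

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        data = self.data + other.data
        return Tensor._make(
            data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return (-self) + as_tensor(other)

    def __mul__(self, other):
        other = as_tensor(other)
        data = self.data * other.data
        return Tensor._make(
            data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        data = self.data / other.data
        return Tensor._make(
            data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __pow__(self, exponent: float):
        data = self.data**exponent
        return Tensor._make(
            data,
            (self,),
            lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def __getitem__(self, key):
        data = self.data[key]

        def grad_fn(g):
            out = np.zeros_like(self.data)
            np.add.at(out, key, g)
            return (out,)

        return Tensor._make(data, (self,), grad_fn)

    # -- reductions / elementwise -------------------------------------------
    def sum(self):
        return Tensor._make(
            np.asarray(self.data.sum()),
            (self,),
            lambda g: (np.broadcast_to(g, self.shape).copy(),),
        )

    def mean(self):
        n = self.data.size
        return Tensor._make(
            np.asarray(self.data.mean()),
            (self,),
            lambda g: (np.broadcast_to(g / n, self.shape).copy(),),
        )

    def abs(self):
        sign = np.sign(self.data)
        return Tensor._make(np.abs(self.data), (self,), lambda g: (g * sign,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def clip(self, lo: float, hi: float):
        inside = (self.data > lo) & (self.data < hi)
        return Tensor._make(
            np.clip(self.data, lo, hi), (self,), lambda g: (g * inside,)
        )

    def reshape(self, *shape):
        old = self.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)

    def grad_fn(g):
        splits = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        return tuple(splits)

    return Tensor._make(data, tuple(tensors), grad_fn)


def crop(x: Tensor, height: int, width: int) -> Tensor:
    """Top-left crop of the two trailing axes."""
    data = x.data[..., :height, :width]

    def grad_fn(g):
        out = np.zeros_like(x.data)
        out[..., :height, :width] = g
        return (out,)

    return Tensor._make(data, (x,), grad_fn)


def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    pos = x.data > 0
    scale = np.where(pos, 1.0, slope).astype(np.float32)
    return Tensor._make(x.data * scale, (x,), lambda g: (g * scale,))


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 1) -> Tensor:
    """2D convolution (cross-correlation), NCHW, zero padding."""
    B, C, H, W = x.shape
    Cout, Cin, k, _ = w.shape
    if Cin != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cin}")
    p, s = padding, stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    Ho, Wo = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B, Ho * Wo, C * k * k
    )
    wm = w.data.reshape(Cout, -1)
    out = cols @ wm.T + b.data[None, None, :]
    out = out.transpose(0, 2, 1).reshape(B, Cout, Ho, Wo)

    def grad_fn(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(B, Ho * Wo, Cout)
        gw = np.einsum("bnc,bnk->ck", g2, cols, optimize=True).reshape(w.shape)
        gb = g.sum(axis=(0, 2, 3))
        gx = None
        if x.requires_grad:
            gcols = (g2 @ wm).reshape(B, Ho, Wo, C, k, k)
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    gxp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += gcols[
                        :, :, :, :, i, j
                    ].transpose(0, 3, 1, 2)
            gx = gxp[:, :, p : p + H, p : p + W] if p else gxp
        return (gx, gw, gb)

    return Tensor._make(out, (x, w, b), grad_fn)


# ---------------------------------------------------------------------------
# box filtering (the B-spline pooling primitive)
# ---------------------------------------------------------------------------


def _box_sum_valid(x: np.ndarray, k: int, axis: int) -> np.ndarray:
    cs = np.cumsum(x, axis=axis, dtype=np.float64)
    zero_shape = list(x.shape)
    zero_shape[axis] = 1
    cs = np.concatenate([np.zeros(zero_shape), cs], axis=axis)
    lead = [slice(None)] * x.ndim
    lead[axis] = slice(k, None)
    head = [slice(None)] * x.ndim
    head[axis] = slice(0, cs.shape[axis] - k)
    return (cs[tuple(lead)] - cs[tuple(head)]).astype(np.float32)


def _box1d(x: np.ndarray, k: int, axis: int) -> np.ndarray:
    """Unit-stride average along ``axis`` with replicate (edge) padding."""
    p = k // 2
    pads = [(0, 0)] * x.ndim
    pads[axis] = (p, p)
    xp = np.pad(x, pads, mode="edge")
    return _box_sum_valid(xp, k, axis) / k


def _box1d_adjoint(g: np.ndarray, k: int, axis: int) -> np.ndarray:
    """Adjoint of :func:`_box1d` (edge padding folds into border samples)."""
    p = k // 2
    pads = [(0, 0)] * g.ndim
    pads[axis] = (k - 1, k - 1)
    gz = np.pad(g, pads)
    gxp = _box_sum_valid(gz, k, axis) / k  # gradient w.r.t. the padded array
    n = g.shape[axis]
    sl = [slice(None)] * g.ndim
    sl[axis] = slice(p, p + n)
    gx = gxp[tuple(sl)].copy()
    if p:
        first = [slice(None)] * g.ndim
        first[axis] = slice(0, p)
        last = [slice(None)] * g.ndim
        last[axis] = slice(p + n, None)
        lo = [slice(None)] * g.ndim
        lo[axis] = slice(0, 1)
        hi = [slice(None)] * g.ndim
        hi[axis] = slice(n - 1, n)
        gx[tuple(lo)] += gxp[tuple(first)].sum(axis=axis, keepdims=True)
        gx[tuple(hi)] += gxp[tuple(last)].sum(axis=axis, keepdims=True)
    return gx


def _avg_pool_once(x: Tensor, kernel: int) -> Tensor:
    data = _box1d(_box1d(x.data, kernel, -1), kernel, -2)

    def grad_fn(g):
        return (_box1d_adjoint(_box1d_adjoint(g, kernel, -2), kernel, -1),)

    return Tensor._make(data, (x,), grad_fn)


def avg_pool_smooth(x: Tensor, kernel: int, passes: int = 1) -> Tensor:
    """``passes`` unit-stride k×k average-pooling passes, replicate padding."""
    if kernel % 2 == 0 or kernel < 1:
        raise ValueError(f"pooling kernel must be odd and >= 1, got {kernel}")
    if passes < 1:
        raise ValueError("passes must be >= 1")
    if kernel == 1:
        return x
    for _ in range(passes):
        x = _avg_pool_once(x, kernel)
    return x


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    if factor < 1:
        raise ValueError("upsampling factor must be >= 1")
    data = np.repeat(np.repeat(x.data, factor, axis=-2), factor, axis=-1)
    shp = x.shape

    def grad_fn(g):
        g = g.reshape(*shp[:-2], shp[-2], factor, shp[-1], factor)
        return (g.sum(axis=(-3, -1)),)

    return Tensor._make(data, (x,), grad_fn)


# ---------------------------------------------------------------------------
# bilinear sampling (the spatial transformer)
# ---------------------------------------------------------------------------


def bilinear_sample(src: Tensor, coords: Tensor) -> Tensor:
    """Sample ``src`` (B,C,h,w) at absolute pixel positions ``coords`` (B,2,H,W).

    ``coords[:, 0]`` holds x (column) and ``coords[:, 1]`` y (row) positions,
    0-based, origin top-left.  Out-of-bounds positions clamp to the border
    (and receive zero positional gradient there).
    """
    B, C, h, w = src.shape
    if coords.shape[0] != B or coords.shape[1] != 2:
        raise ValueError(f"coords must be (B,2,H,W), got {coords.shape}")
    H, W = coords.shape[2], coords.shape[3]
    hw = h * w

    cx = coords.data[:, 0].reshape(B, 1, H * W)
    cy = coords.data[:, 1].reshape(B, 1, H * W)
    inx = (cx >= 0) & (cx <= w - 1)
    iny = (cy >= 0) & (cy <= h - 1)
    cx = np.clip(cx, 0, w - 1)
    cy = np.clip(cy, 0, h - 1)
    x0 = np.minimum(np.floor(cx), w - 2).astype(np.int64) if w > 1 else np.zeros_like(cx, dtype=np.int64)
    y0 = np.minimum(np.floor(cy), h - 2).astype(np.int64) if h > 1 else np.zeros_like(cy, dtype=np.int64)
    fx = (cx - x0).astype(np.float32)
    fy = (cy - y0).astype(np.float32)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)

    flat = src.data.reshape(B, C, hw)
    bI = np.arange(B)[:, None, None]
    cI = np.arange(C)[None, :, None]
    i00 = y0 * w + x0
    i01 = y0 * w + x1
    i10 = y1 * w + x0
    i11 = y1 * w + x1
    v00 = flat[bI, cI, i00]
    v01 = flat[bI, cI, i01]
    v10 = flat[bI, cI, i10]
    v11 = flat[bI, cI, i11]

    w00 = (1 - fy) * (1 - fx)
    w01 = (1 - fy) * fx
    w10 = fy * (1 - fx)
    w11 = fy * fx
    out = (w00 * v00 + w01 * v01 + w10 * v10 + w11 * v11).reshape(B, C, H, W)

    def grad_fn(g):
        g = g.reshape(B, C, H * W)
        gsrc = None
        if src.requires_grad:
            comb_base = (np.arange(B)[:, None, None] * C + np.arange(C)[None, :, None]) * hw
            acc = np.zeros(B * C * hw, dtype=np.float64)
            for idx, wt in ((i00, w00), (i01, w01), (i10, w10), (i11, w11)):
                comb = np.broadcast_to(comb_base + idx, (B, C, H * W))
                acc += np.bincount(
                    comb.ravel(), weights=(g * wt).ravel(), minlength=B * C * hw
                )
            gsrc = acc.reshape(B, C, h, w).astype(np.float32)
        gcoords = None
        if coords.requires_grad:
            dx = ((1 - fy) * (v01 - v00) + fy * (v11 - v10)) * g
            dy = ((1 - fx) * (v10 - v00) + fx * (v11 - v01)) * g
            gx = (dx.sum(axis=1, keepdims=True) * inx).reshape(B, 1, H, W)
            gy = (dy.sum(axis=1, keepdims=True) * iny).reshape(B, 1, H, W)
            gcoords = np.concatenate([gx, gy], axis=1)
        return (gsrc, gcoords)

    return Tensor._make(out, (src, coords), grad_fn)


# ---------------------------------------------------------------------------
# classification head
# ---------------------------------------------------------------------------


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def grad_fn(g):
        return (p * (g - (g * p).sum(axis=axis, keepdims=True)),)

    return Tensor._make(p, (x,), grad_fn)


def gather_class(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Pick ``probs[b, labels[b,i,j], i, j]`` -> (B, H, W)."""
    B, C, H, W = probs.shape
    labels = np.asarray(labels)
    if labels.shape != (B, H, W):
        raise ValueError(f"labels shape {labels.shape} != {(B, H, W)}")
    if labels.max() >= C:
        raise ValueError("label id out of range")
    bI, yI, xI = np.ogrid[:B, :H, :W]
    out = probs.data[bI, labels, yI, xI]

    def grad_fn(g):
        gp = np.zeros_like(probs.data)
        gp[bI, labels, yI, xI] = g
        return (gp,)

    return Tensor._make(out, (probs,), grad_fn)
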