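"""Minimal reverse-mode autodiff over numpy arrays.

Just enough machinery for a small detection network on a CPU: tensors with
gradient tape, broadcasting-aware elementwise ops, dense matmul, im2col
convolution, non-overlapping transposed convolution and max pooling, RoI max
pooling, and numerically stable classification losses.  Everything is
float32 and deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "maxpool2d",
    "roi_pool",
    "gather_rows",
    "relu",
    "bce_with_logits",
    "softmax_cross_entropy",
    "smooth_l1_loss",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    """An n-d array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction -------------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic ----------------------------------------------------------

    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    def __neg__(self):
        return self * Tensor(np.float32(-1.0))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    __radd__ = __add__
    __rmul__ = __mul__

    def pow_const(self, p: float):
        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * p * np.power(self.data, p - 1))

        return Tensor._make(np.power(self.data, p), (self,), backward)

    def matmul(self, other: "Tensor"):
        def backward(out):
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    def reshape(self, *shape):
        orig = self.data.shape

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def sum(self):
        def backward(out):
            if self.requires_grad:
                self._accum(np.full_like(self.data, out.grad))

        return Tensor._make(self.data.sum(), (self,), backward)

    def mean(self):
        n = self.data.size

        def backward(out):
            if self.requires_grad:
                self._accum(np.full_like(self.data, out.grad / n))

        return Tensor._make(self.data.mean(), (self,), backward)

    def mean_axis(self, axis: int, keepdims: bool = True):
        n = self.data.shape[axis]

        def backward(out):
            if self.requires_grad:
                g = out.grad if keepdims else np.expand_dims(out.grad, axis)
                self._accum(np.broadcast_to(g / n, self.data.shape).copy())

        return Tensor._make(self.data.mean(axis=axis, keepdims=keepdims), (self,), backward)

    # -- autodiff ------------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node)
        # free the tape
        for node in topo:
            node._backward = None
            node._parents = ()


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(out):
        if x.requires_grad:
            x._accum(out.grad * mask)

    return Tensor._make(x.data * mask, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(out):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(a, b)
                t._accum(out.grad[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``x[idx]`` of a 2-D tensor (duplicates allowed)."""
    idx = np.asarray(idx, dtype=int)

    def backward(out):
        if x.requires_grad:
            g = np.zeros_like(x.data)
            np.add.at(g, idx, out.grad)
            x._accum(g)

    return Tensor._make(x.data[idx], (x,), backward)


# ---------------------------------------------------------------------------
# convolution (im2col)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (n, c, ho, wo, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, x_shape, kh, kw, stride, pad, ho, wo):
    n, c, h, w = x_shape
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcols[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution; ``weight`` is ``(F, C, kh, kw)``, ``bias`` ``(F,)``."""
    f, c, kh, kw = weight.data.shape
    n = x.data.shape[0]
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(f, -1)
    out = cols @ wmat.T
    if bias is not None:
        out += bias.data
    out = out.reshape(n, ho, wo, f).transpose(0, 3, 1, 2)

    parents = (x, weight) + ((bias,) if bias is not None else ())

    def backward(o):
        dout = o.grad.transpose(0, 2, 3, 1).reshape(-1, f)
        if weight.requires_grad:
            weight._accum((dout.T @ cols).reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(dout.sum(axis=0))
        if x.requires_grad:
            dcols = dout @ wmat
            x._accum(_col2im(dcols, x.data.shape, kh, kw, stride, pad, ho, wo))

    return Tensor._make(out, parents, backward)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int) -> Tensor:
    """Transposed convolution with kernel == stride (exact, non-overlapping upsampling).

    ``weight`` is ``(C_in, F, s, s)``; output is ``(N, F, H*s, W*s)``.
    """
    c_in, f, kh, kw = weight.data.shape
    if kh != stride or kw != stride:
        raise ValueError("conv_transpose2d requires kernel size == stride")
    n, c, h, w = x.data.shape
    # y[n, f, i*s+u, j*s+v] = sum_c x[n, c, i, j] * W[c, f, u, v]
    y = np.einsum("nchw,cfuv->nfhuwv", x.data, weight.data, optimize=True)
    y = y.reshape(n, f, h * stride, w * stride)
    if bias is not None:
        y = y + bias.data[None, :, None, None]

    parents = (x, weight) + ((bias,) if bias is not None else ())

    def backward(o):
        g = o.grad.reshape(n, f, h, stride, w, stride)
        if x.requires_grad:
            x._accum(np.einsum("nfhuwv,cfuv->nchw", g, weight.data, optimize=True))
        if weight.requires_grad:
            weight._accum(np.einsum("nchw,nfhuwv->cfuv", x.data, g, optimize=True))
        if bias is not None and bias.requires_grad:
            bias._accum(o.grad.sum(axis=(0, 2, 3)))

    return Tensor._make(y, parents, backward)


def maxpool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping ``k x k`` max pooling (pads with -inf if needed)."""
    n, c, h, w = x.data.shape
    ho, wo = -(-h // k), -(-w // k)
    ph, pw = ho * k - h, wo * k - w
    xp = x.data
    if ph or pw:
        xp = np.pad(xp, ((0, 0), (0, 0), (0, ph), (0, pw)), constant_values=-np.inf)
    r = xp.reshape(n, c, ho, k, wo, k).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, k * k)
    arg = r.argmax(axis=-1)
    out = np.take_along_axis(r, arg[..., None], axis=-1)[..., 0]

    def backward(o):
        if not x.requires_grad:
            return
        dr = np.zeros_like(r)
        np.put_along_axis(dr, arg[..., None], o.grad[..., None], axis=-1)
        dxp = dr.reshape(n, c, ho, wo, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho * k, wo * k)
        x._accum(dxp[:, :, :h, :w])

    return Tensor._make(out, (x,), backward)


def roi_pool(feature: Tensor, rois: np.ndarray, out_size: int = 7) -> Tensor:
    """RoI max pooling over a ``(1, C, H, W)`` feature map.

    ``rois`` is ``(R, 4)`` in feature-map coordinates ``(x1, y1, x2, y2)``,
    half-open.  Each RoI is divided into an ``out_size x out_size`` grid and
    max-pooled per bin; empty bins produce 0.
    """
    if feature.data.shape[0] != 1:
        raise ValueError("roi_pool expects batch size 1")
    _, c, h, w = feature.data.shape
    rois = np.asarray(rois, dtype=float)
    nr = rois.shape[0]
    out = np.zeros((nr, c, out_size, out_size), dtype=np.float32)
    argmax = np.full((nr, c, out_size, out_size), -1, dtype=np.int64)
    fmap = feature.data[0].reshape(c, -1)
    for r in range(nr):
        x1 = int(np.clip(np.floor(rois[r, 0]), 0, w - 1))
        y1 = int(np.clip(np.floor(rois[r, 1]), 0, h - 1))
        x2 = int(np.clip(np.ceil(rois[r, 2]), x1 + 1, w))
        y2 = int(np.clip(np.ceil(rois[r, 3]), y1 + 1, h))
        xs = np.round(np.linspace(x1, x2, out_size + 1)).astype(int)
        ys = np.round(np.linspace(y1, y2, out_size + 1)).astype(int)
        for i in range(out_size):
            for j in range(out_size):
                ya, yb = ys[i], max(ys[i + 1], ys[i] + 1)
                xa, xb = xs[j], max(xs[j + 1], xs[j] + 1)
                yb, xb = min(yb, h), min(xb, w)
                if ya >= yb or xa >= xb:
                    continue
                patch = feature.data[0, :, ya:yb, xa:xb].reshape(c, -1)
                loc = patch.argmax(axis=1)
                yy = ya + loc // (xb - xa)
                xx = xa + loc % (xb - xa)
                flat = yy * w + xx
                out[r, :, i, j] = fmap[np.arange(c), flat]
                argmax[r, :, i, j] = flat

    def backward(o):
        if not feature.requires_grad:
            return
        g = np.zeros((c, h * w), dtype=np.float32)
        valid = argmax >= 0
        ch_idx = np.broadcast_to(np.arange(c)[None, :, None, None], argmax.shape)
        np.add.at(g, (ch_idx[valid], argmax[valid]), o.grad[valid])
        feature._accum(g.reshape(1, c, h, w))

    return Tensor._make(out, (feature,), backward)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Sum of binary cross-entropies (log loss) over all elements, stable form."""
    t = np.asarray(targets, dtype=np.float32)
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))

    def backward(o):
        if logits.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-z))
            logits._accum(o.grad * (sig - t))

    return Tensor._make(loss.sum(), (logits,), backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Sum of softmax cross-entropies; ``logits`` ``(N, C)``, ``labels`` ``(N,)``."""
    labels = np.asarray(labels, dtype=int)
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    loss = -(np.log(np.maximum(p[np.arange(n), labels], 1e-30))).sum()

    def backward(o):
        if logits.requires_grad:
            g = p.copy()
            g[np.arange(n), labels] -= 1.0
            logits._accum(o.grad * g)

    return Tensor._make(np.float32(loss), (logits,), backward)


def smooth_l1_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Sum of elementwise Smooth L1 (0.5 x^2 if |x| < 1 else |x| - 0.5)."""
    t = np.asarray(target, dtype=np.float32)
    x = pred.data - t
    ax = np.abs(x)
    loss = np.where(ax < 1.0, 0.5 * x * x, ax - 0.5)

    def backward(o):
        if pred.requires_grad:
            pred._accum(o.grad * np.where(ax < 1.0, x, np.sign(x)))

    return Tensor._make(loss.sum(), (pred,), backward)
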