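"""Compact reverse-mode autodiff core for the segmentation network.

Arrays are float32 numpy throughout.  A :class:`Tensor` wraps an ndarray and,
when gradients are enabled, a backward closure plus references to its parent
tensors; :meth:`Tensor.backward` runs the closures in reverse topological
order.  Only the operations the network needs are provided (convolutions,
batch norm, the MobileNetV3 activations, pooling means, concatenation,
bilinear resizing and a fused softmax cross-entropy).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference / metrics)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def grad_enabled() -> bool:
    return _grad_enabled


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free intermediate graph state eagerly
            node._backward = None


def _result(data: np.ndarray, parents: Sequence[Tensor],
            backward: Callable[[np.ndarray], None] | None) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad:
        t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.astype(np.float32, copy=False)


# ---------------------------------------------------------------------------
# elementwise / arithmetic


def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _result(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _result(data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    data = np.where(mask, x.data, 0.0).astype(np.float32)

    def backward(g):
        _accum(x, g * mask)

    return _result(data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        _accum(x, g * data * (1.0 - data))

    return _result(data, (x,), backward)


def hardsigmoid(x: Tensor) -> Tensor:
    # relu6(x + 3) / 6
    data = np.clip((x.data + 3.0) / 6.0, 0.0, 1.0).astype(np.float32)

    def backward(g):
        inside = (x.data > -3.0) & (x.data < 3.0)
        _accum(x, g * inside / 6.0)

    return _result(data, (x,), backward)


def hardswish(x: Tensor) -> Tensor:
    hs = np.clip((x.data + 3.0) / 6.0, 0.0, 1.0)
    data = (x.data * hs).astype(np.float32)

    def backward(g):
        d = np.where(x.data <= -3.0, 0.0,
                     np.where(x.data >= 3.0, 1.0, (2.0 * x.data + 3.0) / 6.0))
        _accum(x, g * d.astype(np.float32))

    return _result(data, (x,), backward)


def mean(x: Tensor, axes: tuple[int, ...], keepdims: bool = True) -> Tensor:
    data = x.data.mean(axis=axes, keepdims=keepdims)
    count = np.prod([x.data.shape[a] for a in axes])

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        _accum(x, np.broadcast_to(g / count, x.data.shape).astype(np.float32))

    return _result(data, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        offset = 0
        for t, s in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offset, offset + s)
            _accum(t, g[tuple(sl)])
            offset += s

    return _result(data, tuple(tensors), backward)


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)
    data = x.data[sl]

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[sl] = g
        _accum(x, gx)

    return _result(data, (x,), backward)


def swap_hw(x: Tensor) -> Tensor:
    """Transpose the two trailing spatial axes of an NCHW tensor."""
    data = np.ascontiguousarray(x.data.transpose(0, 1, 3, 2))

    def backward(g):
        _accum(x, np.ascontiguousarray(g.transpose(0, 1, 3, 2)))

    return _result(data, (x,), backward)


# ---------------------------------------------------------------------------
# convolution


def _pad_nchw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """2-D convolution on NCHW input.

    ``w`` has shape (O, C//groups, k, k).  Only groups == 1 (dense) and
    groups == C (depthwise) are supported — the only two cases MobileNetV3
    uses.
    """
    n, c, _, _ = x.data.shape
    o, cg, kh, kw = w.data.shape
    if kh != kw:
        raise ValueError("only square kernels are supported")
    k, s, p = kh, stride, padding
    if groups == 1:
        if cg != c:
            raise ValueError(f"weight expects {cg} input channels, got {c}")
    elif groups == c:
        if not (cg == 1 and o == c):
            raise ValueError("depthwise conv requires weight shape (C,1,k,k)")
    else:
        raise ValueError("groups must be 1 or equal to input channels")

    if k == 1 and groups == 1:
        xs = x.data[:, :, ::s, ::s] if s > 1 else x.data
        xs = np.ascontiguousarray(xs)
        hw = xs.shape[2] * xs.shape[3]
        w2 = w.data.reshape(o, c)
        # per-sample GEMM on contiguous (C, H*W) views: no transposes/copies
        xm = xs.reshape(n, c, hw)
        out = np.empty((n, o, xs.shape[2], xs.shape[3]), dtype=np.float32)
        om = out.reshape(n, o, hw)
        for i in range(n):
            np.matmul(w2, xm[i], out=om[i])
        if b is not None:
            out += b.data.reshape(1, o, 1, 1)

        def backward(g):
            gm = np.ascontiguousarray(g).reshape(n, o, hw)
            gw = np.zeros((o, c), dtype=np.float32)
            for i in range(n):
                gw += gm[i] @ xm[i].transpose()
            _accum(w, gw.reshape(w.data.shape))
            if b is not None:
                _accum(b, g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gxs = np.empty_like(xs)
                gxm = gxs.reshape(n, c, hw)
                w2t = np.ascontiguousarray(w2.transpose())
                for i in range(n):
                    np.matmul(w2t, gm[i], out=gxm[i])
                if s > 1:
                    gx = np.zeros_like(x.data)
                    gx[:, :, ::s, ::s] = gxs
                else:
                    gx = gxs
                _accum(x, gx)

        parents = (x, w) if b is None else (x, w, b)
        return _result(out, parents, backward)

    # k x k convs run as a shift-and-accumulate over the k^2 kernel offsets:
    # each offset contributes an elementwise (depthwise) or channel-mixing
    # 1x1 (dense) product on a strided slice of the padded input.  This keeps
    # every inner operation a contiguous elementwise op or GEMM and avoids
    # materializing im2col windows.
    xp = _pad_nchw(x.data, p)
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - k) // s + 1
    wo = (wp - k) // s + 1

    def _slice(arr, i, j):
        return arr[:, :, i:i + ho * s:s, j:j + wo * s:s]

    if groups == c:  # depthwise
        wdw = w.data.reshape(c, k, k)
        out = np.zeros((n, c, ho, wo), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                out += _slice(xp, i, j) * wdw[None, :, i, j, None, None]
        if b is not None:
            out += b.data.reshape(1, c, 1, 1)

        def backward(g):
            gw = np.empty((c, k, k), dtype=np.float32)
            for i in range(k):
                for j in range(k):
                    gw[:, i, j] = (_slice(xp, i, j) * g).sum(axis=(0, 2, 3))
            _accum(w, gw.reshape(w.data.shape))
            if b is not None:
                _accum(b, g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gxp = np.zeros((n, c, hp, wp), dtype=np.float32)
                for i in range(k):
                    for j in range(k):
                        _slice(gxp, i, j)[...] += (
                            g * wdw[None, :, i, j, None, None])
                gx = gxp[:, :, p:hp - p, p:wp - p] if p else gxp
                _accum(x, gx)

        parents = (x, w) if b is None else (x, w, b)
        return _result(out, parents, backward)

    # dense k x k conv: sum of k^2 pointwise GEMMs
    out = np.zeros((n, ho, wo, o), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            out += np.tensordot(_slice(xp, i, j), w.data[:, :, i, j],
                                axes=([1], [1]))
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    if b is not None:
        out += b.data.reshape(1, o, 1, 1)

    def backward(g):
        gw = np.empty((o, c, k, k), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                gw[:, :, i, j] = np.tensordot(
                    g, _slice(xp, i, j), axes=([0, 2, 3], [0, 2, 3]))
        _accum(w, gw)
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros((n, c, hp, wp), dtype=np.float32)
            for i in range(k):
                for j in range(k):
                    gc = np.tensordot(g, w.data[:, :, i, j],
                                      axes=([1], [0]))  # N,Ho,Wo,C
                    _slice(gxp, i, j)[...] += gc.transpose(0, 3, 1, 2)
            gx = gxp[:, :, p:hp - p, p:wp - p] if p else gxp
            _accum(x, gx)

    parents = (x, w) if b is None else (x, w, b)
    return _result(out, parents, backward)


# ---------------------------------------------------------------------------
# batch normalization


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch norm on NCHW input; updates running stats in place."""
    c = x.data.shape[1]
    gview = gamma.data.reshape(1, c, 1, 1)
    bview = beta.data.reshape(1, c, 1, 1)
    if training:
        axes = (0, 2, 3)
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        unbiased = var * (m / max(m - 1, 1))
        running_var *= (1.0 - momentum)
        running_var += momentum * unbiased
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
        out = (gview * xhat + bview).astype(np.float32)

        def backward(g):
            _accum(gamma, (g * xhat).sum(axis=axes))
            _accum(beta, g.sum(axis=axes))
            if x.requires_grad:
                gm = g.mean(axis=axes, keepdims=True)
                gxm = (g * xhat).mean(axis=axes, keepdims=True)
                gx = (gview * inv.reshape(1, c, 1, 1)) * (g - gm - xhat * gxm)
                _accum(x, gx.astype(np.float32))

        return _result(out, (x, gamma, beta), backward)

    inv = (1.0 / np.sqrt(running_var + eps)).reshape(1, c, 1, 1)
    mu = running_mean.reshape(1, c, 1, 1)
    out = (gview * (x.data - mu) * inv + bview).astype(np.float32)
    xhat_eval = (x.data - mu) * inv

    def backward(g):
        _accum(gamma, (g * xhat_eval).sum(axis=(0, 2, 3)))
        _accum(beta, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            _accum(x, (g * gview * inv).astype(np.float32))

    return _result(out, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# bilinear resize

_resize_cache: dict[tuple[int, int], np.ndarray] = {}


def _resize_matrix(src: int, dst: int) -> np.ndarray:
    """Row-interpolation matrix (dst x src), half-pixel centers."""
    key = (src, dst)
    mat = _resize_cache.get(key)
    if mat is None:
        pos = (np.arange(dst, dtype=np.float64) + 0.5) * (src / dst) - 0.5
        pos = np.clip(pos, 0.0, src - 1.0)
        lo = np.floor(pos).astype(np.int64)
        hi = np.minimum(lo + 1, src - 1)
        frac = (pos - lo).astype(np.float64)
        mat = np.zeros((dst, src), dtype=np.float32)
        rows = np.arange(dst)
        np.add.at(mat, (rows, lo), (1.0 - frac).astype(np.float32))
        np.add.at(mat, (rows, hi), frac.astype(np.float32))
        _resize_cache[key] = mat
    return mat


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of an NCHW tensor (half-pixel-aligned sampling)."""
    _, _, h, w = x.data.shape
    mh = _resize_matrix(h, out_h)
    mw = _resize_matrix(w, out_w)
    tmp = np.tensordot(x.data, mh, axes=([2], [1]))       # N,C,W,Ho
    out = np.tensordot(tmp, mw, axes=([2], [1]))          # N,C,Ho,Wo
    out = np.ascontiguousarray(out.astype(np.float32))

    def backward(g):
        t = np.tensordot(g, mw, axes=([3], [0]))          # N,C,Ho,W
        gx = np.tensordot(t, mh, axes=([2], [0]))         # N,C,W,H
        _accum(x, np.ascontiguousarray(
            gx.transpose(0, 1, 3, 2).astype(np.float32)))

    return _result(out, (x,), backward)


# ---------------------------------------------------------------------------
# loss


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy (nats) of NCHW logits vs NHW int labels."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n, c, h, w = probs.shape
    total = n * h * w
    idx_n, idx_h, idx_w = np.meshgrid(
        np.arange(n), np.arange(h), np.arange(w), indexing="ij")
    picked = probs[idx_n, labels, idx_h, idx_w]
    loss = -np.log(np.maximum(picked, 1e-12)).sum() / total

    def backward(g):
        grad = probs.copy()
        grad[idx_n, labels, idx_h, idx_w] -= 1.0
        _accum(logits, (g * grad / total).astype(np.float32))

    return _result(np.float32(loss), (logits,), backward)
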