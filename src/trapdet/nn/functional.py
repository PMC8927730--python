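"""Differentiable operations: convolutions, resampling, activations, losses.

Convolutions are evaluated as a sum of per-kernel-tap GEMMs over shifted
strided views of the (padded) input.  This avoids materializing an im2col
buffer, keeps peak memory close to the size of the activations themselves,
and routes all heavy work through BLAS.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .tensor import Tensor, as_tensor

__all__ = [
    "relu",
    "sigmoid",
    "exp",
    "log",
    "absolute",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "bilinear_resize",
    "max_pool_stride2",
    "global_avg_pool",
    "global_max_pool",
    "softmax",
    "softmax_cross_entropy",
    "bce_with_logits",
    "l1_loss",
    "smooth_l1_loss",
]


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accumulate(g * mask)

    return Tensor._result(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    d = x.data
    out = np.where(d >= 0, 1.0 / (1.0 + np.exp(-d)), np.exp(d) / (1.0 + np.exp(d)))
    out = out.astype(np.float32)

    def backward(g):
        x._accumulate(g * out * (1.0 - out))

    return Tensor._result(out, (x,), backward)


def exp(x: Tensor) -> Tensor:
    out = np.exp(x.data)

    def backward(g):
        x._accumulate(g * out)

    return Tensor._result(out, (x,), backward)


def log(x: Tensor) -> Tensor:
    def backward(g):
        x._accumulate(g / x.data)

    return Tensor._result(np.log(x.data), (x,), backward)


def absolute(x: Tensor) -> Tensor:
    def backward(g):
        x._accumulate(g * np.sign(x.data))

    return Tensor._result(np.abs(x.data), (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._result(data, tuple(tensors), backward)


# -- convolutions ------------------------------------------------------


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Optional[Tensor] = None,
    stride: int = 1,
    padding: int = 0,
) -> Tensor:
    """2-D convolution, NCHW input, OIHW weight."""
    n, c, h, wid = x.shape
    o, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, weight expects {ci}")
    s, p = stride, padding
    oh = (h + 2 * p - kh) // s + 1
    ow = (wid + 2 * p - kw) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    out = np.zeros((n, o, oh, ow), dtype=np.float32)
    for di in range(kh):
        for dj in range(kw):
            view = xp[:, :, di : di + s * oh : s, dj : dj + s * ow : s]
            tap = np.tensordot(w.data[:, :, di, dj], view, axes=([1], [1]))
            out += tap.transpose(1, 0, 2, 3)
    if b is not None:
        out += b.data.reshape(1, o, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if x.requires_grad:
            dxp = np.zeros_like(xp)
        for di in range(kh):
            for dj in range(kw):
                sl = (
                    slice(None),
                    slice(None),
                    slice(di, di + s * oh, s),
                    slice(dj, dj + s * ow, s),
                )
                if w.requires_grad:
                    dw_tap = np.tensordot(g, xp[sl], axes=([0, 2, 3], [0, 2, 3]))
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[:, :, di, dj] += dw_tap
                if x.requires_grad:
                    dx_tap = np.tensordot(
                        w.data[:, :, di, dj], g, axes=([0], [1])
                    )
                    dxp[sl] += dx_tap.transpose(1, 0, 2, 3)
        if x.requires_grad:
            x._accumulate(dxp[:, :, p : p + h, p : p + wid] if p else dxp)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._result(out, parents, backward)


def conv_transpose2d(
    x: Tensor,
    w: Tensor,
    b: Optional[Tensor] = None,
    stride: int = 2,
    padding: int = 1,
    output_size: Optional[tuple[int, int]] = None,
) -> Tensor:
    """Transposed convolution, NCHW input, IOHW weight.

    With kernel 4, stride 2, padding 1 the output is exactly twice the input
    grid; ``output_size`` optionally crops the bottom/right edge (used to hit
    ceil-division grids of odd image sizes).
    """
    n, c, h, wid = x.shape
    ci, o, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, weight expects {ci}")
    s, p = stride, padding
    hf = (h - 1) * s + kh
    wf = (wid - 1) * s + kw
    buf = np.zeros((n, o, hf, wf), dtype=np.float32)
    for di in range(kh):
        for dj in range(kw):
            tap = np.tensordot(w.data[:, :, di, dj], x.data, axes=([0], [1]))
            buf[:, :, di : di + s * h : s, dj : dj + s * wid : s] += tap.transpose(
                1, 0, 2, 3
            )
    oh, ow = hf - 2 * p, wf - 2 * p
    if output_size is not None:
        if output_size[0] > oh or output_size[1] > ow:
            raise ValueError("output_size may only crop, not grow")
        oh, ow = output_size
    out = buf[:, :, p : p + oh, p : p + ow].copy()
    if b is not None:
        out += b.data.reshape(1, o, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gfull = np.zeros((n, o, hf, wf), dtype=np.float32)
        gfull[:, :, p : p + oh, p : p + ow] = g
        for di in range(kh):
            for dj in range(kw):
                gview = gfull[:, :, di : di + s * h : s, dj : dj + s * wid : s]
                if x.requires_grad:
                    dx_tap = np.tensordot(
                        w.data[:, :, di, dj], gview, axes=([1], [1])
                    )
                    x._accumulate(dx_tap.transpose(1, 0, 2, 3))
                if w.requires_grad:
                    dw_tap = np.tensordot(
                        x.data, gview, axes=([0, 2, 3], [0, 2, 3])
                    )
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[:, :, di, dj] += dw_tap
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._result(out, parents, backward)


# -- resampling and pooling -------------------------------------------


def _linear_coords(n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Half-pixel-center source coordinates for 1-D linear resampling."""
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(np.int64)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (src - lo).astype(np.float32)
    return lo, hi, frac


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of an NCHW tensor with half-pixel-center sampling."""
    n, c, h, w = x.shape
    if (h, w) == (out_h, out_w):
        return x * 1.0
    y0, y1, fy = _linear_coords(h, out_h)
    x0, x1, fx = _linear_coords(w, out_w)
    wy = fy[:, None]
    wx = fx[None, :]
    w00 = (1 - wy) * (1 - wx)
    w01 = (1 - wy) * wx
    w10 = wy * (1 - wx)
    w11 = wy * wx
    d = x.data
    out = (
        d[:, :, y0[:, None], x0[None, :]] * w00
        + d[:, :, y0[:, None], x1[None, :]] * w01
        + d[:, :, y1[:, None], x0[None, :]] * w10
        + d[:, :, y1[:, None], x1[None, :]] * w11
    ).astype(np.float32)

    def backward(g):
        buf = np.zeros_like(x.data)
        sl = (slice(None), slice(None))
        np.add.at(buf, sl + (y0[:, None], x0[None, :]), g * w00)
        np.add.at(buf, sl + (y0[:, None], x1[None, :]), g * w01)
        np.add.at(buf, sl + (y1[:, None], x0[None, :]), g * w10)
        np.add.at(buf, sl + (y1[:, None], x1[None, :]), g * w11)
        x._accumulate(buf)

    return Tensor._result(out, (x,), backward)


def max_pool_stride2(x: Tensor) -> Tensor:
    """Kernel-1 stride-2 subsampling (the extra-top-level convention);
    output grid is the ceil-half of the input grid."""
    return x[:, :, ::2, ::2]


def global_avg_pool(x: Tensor) -> Tensor:
    """NCHW -> NC mean over positions."""
    return x.mean(axis=(2, 3))


def global_max_pool(x: Tensor) -> Tensor:
    """NCHW -> NC max over positions."""
    n, c, h, w = x.shape
    return x.reshape(n, c, h * w).max(axis=2)


# -- losses ------------------------------------------------------------


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = (e / e.sum(axis=axis, keepdims=True)).astype(np.float32)

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        x._accumulate(out * (g - dot))

    return Tensor._result(out, (x,), backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy between row-wise softmax and integer labels."""
    labels = np.asarray(labels, dtype=np.int64)
    n = logits.shape[0]
    shifted = logits.data - logits.data.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1))
    nll = logz - shifted[np.arange(n), labels]
    probs = np.exp(shifted - logz[:, None])

    def backward(g):
        d = probs.copy()
        d[np.arange(n), labels] -= 1.0
        logits._accumulate(g * d / n)

    return Tensor._result(np.float32(nll.mean()), (logits,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits (numerically stable form)."""
    t = np.asarray(targets, dtype=np.float32)
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    n = z.size
    sig = 1.0 / (1.0 + np.exp(-z))

    def backward(g):
        logits._accumulate(g * (sig - t) / n)

    return Tensor._result(np.float32(loss.mean()), (logits,), backward)


def l1_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean absolute error (used for RPN box regression)."""
    t = np.asarray(target, dtype=np.float32)
    d = pred.data - t
    n = d.size

    def backward(g):
        pred._accumulate(g * np.sign(d) / n)

    return Tensor._result(np.float32(np.abs(d).mean()), (pred,), backward)


def smooth_l1_loss(pred: Tensor, target: np.ndarray, beta: float = 1.0) -> Tensor:
    """Huber-style loss, quadratic within ``beta`` of zero (R-CNN head)."""
    t = np.asarray(target, dtype=np.float32)
    d = pred.data - t
    ad = np.abs(d)
    loss = np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta)
    n = d.size

    def backward(g):
        grad = np.where(ad < beta, d / beta, np.sign(d))
        pred._accumulate(g * grad / n)

    return Tensor._result(np.float32(loss.mean()), (pred,), backward)
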