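"""Structured ops on Tensors: convolution, transposed convolution, pooling,
normalization, and classification losses.  Layout is NCHW throughout."""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, log_softmax

__all__ = [
    "conv2d",
    "conv_transpose2d",
    "avg_pool2d",
    "max_pool2d",
    "batch_norm2d",
    "layer_norm",
    "cross_entropy",
]


def _pair(v) -> Tuple[int, int]:
    return (v, v) if isinstance(v, int) else tuple(v)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N, C, H, W) -> columns (N, Ho, Wo, C, kh, kw) plus output geometry."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # N,C,Ho*,Wo*,kh,kw
    win = win[:, :, ::stride, ::stride]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)), x.shape


def _col2im(
    cols: np.ndarray,
    x_shape: Tuple[int, ...],
    kh: int,
    kw: int,
    stride: int,
    pad: int,
) -> np.ndarray:
    """Scatter-add columns (N, Ho, Wo, C, kh, kw) back to (N, C, H, W)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho, wo = cols.shape[1], cols.shape[2]
    buf = np.zeros((n, c, hp * wp))
    ii = (stride * np.arange(ho))[:, None, None, None] + np.arange(kh)[None, None, :, None]
    jj = (stride * np.arange(wo))[None, :, None, None] + np.arange(kw)[None, None, None, :]
    flat = (ii * wp + jj).reshape(-1)  # (Ho*Wo*kh*kw,)
    vals = cols.transpose(0, 3, 1, 2, 4, 5).reshape(n, c, -1)
    np.add.at(buf, (np.arange(n)[:, None, None], np.arange(c)[None, :, None], flat[None, None, :]), vals)
    buf = buf.reshape(n, c, hp, wp)
    if pad:
        buf = buf[:, :, pad:-pad, pad:-pad]
    return buf


def conv2d(
    x: Tensor, weight: Tensor, bias: Optional[Tensor] = None,
    stride: int = 1, padding: int = 0,
) -> Tensor:
    """2-D correlation; weight (Cout, Cin, kh, kw)."""
    co, ci, kh, kw = weight.shape
    cols, padded_shape = _im2col(x.data, kh, kw, stride, padding)
    n, ho, wo = cols.shape[0], cols.shape[1], cols.shape[2]
    cols2 = cols.reshape(n * ho * wo, ci * kh * kw)
    wmat = weight.data.reshape(co, -1)
    out_data = (cols2 @ wmat.T).reshape(n, ho, wo, co).transpose(0, 3, 1, 2)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(
        out_data,
        requires_grad=any(p.requires_grad for p in parents),
        _prev=parents,
    )

    def _bwd(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, co)
        if weight.requires_grad:
            weight._accumulate((gmat.T @ cols2).reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(n, ho, wo, ci, kh, kw)
            x._accumulate(_col2im(dcols, x.shape, kh, kw, stride, padding))

    out._backward = _bwd
    return out


def conv_transpose2d(
    x: Tensor, weight: Tensor, bias: Optional[Tensor] = None,
    stride: int = 1, padding: int = 0,
) -> Tensor:
    """Transposed convolution; weight (Cin, Cout, kh, kw).

    Output side = (H − 1)·stride − 2·padding + k.
    """
    ci, co, kh, kw = weight.shape
    n, _, h, w = x.shape
    ho = (h - 1) * stride - 2 * padding + kh
    wo = (w - 1) * stride - 2 * padding + kw
    xmat = x.data.transpose(0, 2, 3, 1).reshape(n * h * w, ci)
    wmat = weight.data.reshape(ci, co * kh * kw)
    cols = (xmat @ wmat).reshape(n, h, w, co, kh, kw)
    out_data = _col2im(cols, (n, co, ho, wo), kh, kw, stride, padding)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(
        out_data,
        requires_grad=any(p.requires_grad for p in parents),
        _prev=parents,
    )

    def _bwd(g):
        gcols, _ = _im2col(g, kh, kw, stride, padding)  # (N, H, W, Co, kh, kw)
        gcols2 = gcols.reshape(n * h * w, co * kh * kw)
        if x.requires_grad:
            x._accumulate(
                (gcols2 @ wmat.T).reshape(n, h, w, ci).transpose(0, 3, 1, 2)
            )
        if weight.requires_grad:
            weight._accumulate((xmat.T @ gcols2).reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    out._backward = _bwd
    return out


def avg_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    """Average pooling with count_include_pad semantics."""
    cols, _ = _im2col(x.data, kernel, kernel, stride, padding)  # N,Ho,Wo,C,kh,kw
    out_data = cols.mean(axis=(4, 5)).transpose(0, 3, 1, 2)
    out = Tensor(out_data, requires_grad=x.requires_grad, _prev=(x,))

    def _bwd(g):
        if not x.requires_grad:
            return
        n, c, ho, wo = g.shape
        gc = np.broadcast_to(
            g.transpose(0, 2, 3, 1)[..., None, None] / (kernel * kernel),
            (n, ho, wo, c, kernel, kernel),
        )
        x._accumulate(_col2im(gc, x.shape, kernel, kernel, stride, padding))

    out._backward = _bwd
    return out


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    cols, _ = _im2col(x.data, kernel, kernel, stride, padding)
    n, ho, wo, c = cols.shape[:4]
    flat = cols.reshape(n, ho, wo, c, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0].transpose(
        0, 3, 1, 2
    )
    out = Tensor(out_data, requires_grad=x.requires_grad, _prev=(x,))

    def _bwd(g):
        if not x.requires_grad:
            return
        gc = np.zeros((n, ho, wo, c, kernel * kernel))
        np.put_along_axis(gc, arg[..., None], g.transpose(0, 2, 3, 1)[..., None], axis=-1)
        x._accumulate(
            _col2im(gc.reshape(n, ho, wo, c, kernel, kernel), x.shape, kernel, kernel, stride, padding)
        )

    out._backward = _bwd
    return out


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Channelwise batch normalization; updates running stats in place when
    training."""
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    parents = (x, gamma, beta)
    out = Tensor(
        out_data, requires_grad=any(p.requires_grad for p in parents), _prev=parents
    )
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def _bwd(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = g * gamma.data[None, :, None, None]
            if training:
                s1 = gx.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gx * xhat).sum(axis=(0, 2, 3), keepdims=True)
                x._accumulate(
                    inv[None, :, None, None] * (gx - s1 / m - xhat * s2 / m)
                )
            else:
                x._accumulate(gx * inv[None, :, None, None])

    out._backward = _bwd
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalization over the last axis."""
    mean = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv
    out_data = gamma.data * xhat + beta.data
    parents = (x, gamma, beta)
    out = Tensor(
        out_data, requires_grad=any(p.requires_grad for p in parents), _prev=parents
    )
    d = x.data.shape[-1]

    def _bwd(g):
        if gamma.requires_grad:
            gamma._accumulate(
                (g * xhat).sum(axis=tuple(range(g.ndim - 1)))
            )
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=tuple(range(g.ndim - 1))))
        if x.requires_grad:
            gx = g * gamma.data
            s1 = gx.sum(axis=-1, keepdims=True)
            s2 = (gx * xhat).sum(axis=-1, keepdims=True)
            x._accumulate(inv * (gx - s1 / d - xhat * s2 / d))

    out._backward = _bwd
    return out


def cross_entropy(
    logits: Tensor, targets: np.ndarray, class_weights: Optional[np.ndarray] = None
) -> Tensor:
    """Weighted mean cross-entropy; logits (N, C), integer targets (N,)."""
    targets = np.asarray(targets, dtype=int)
    n, c = logits.shape
    logp = log_softmax(logits, axis=-1)
    if class_weights is None:
        class_weights = np.ones(c)
    w = class_weights[targets]
    picked = logp[np.arange(n), targets]
    return -(picked * Tensor(w)).sum() / float(w.sum())
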