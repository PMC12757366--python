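"""Convolution, pooling, resampling and batch-norm primitives.

Convolutions are evaluated as im2col + BLAS matmul; the backward pass
scatters gradients back with per-kernel-offset slice additions (no
`np.add.at` on hot paths).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int,
            ho: int, wo: int) -> np.ndarray:
    """[B,C,Hp,Wp] -> [B, C, kh, kw, ho, wo] view-backed copy."""
    b, c = xp.shape[:2]
    col = np.empty((b, c, kh, kw, ho, wo), dtype=xp.dtype)
    for i in range(kh):
        i_end = i + ho * stride
        for j in range(kw):
            j_end = j + wo * stride
            col[:, :, i, j] = xp[:, :, i:i_end:stride, j:j_end:stride]
    return col


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride/padding."""
    B, C, H, W = x.shape
    O, Cw, kh, kw = w.shape
    if C != Cw:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Cw}")
    ho = (H + 2 * padding - kh) // stride + 1
    wo = (W + 2 * padding - kw) // stride + 1
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    col = _im2col(xp, kh, kw, stride, ho, wo)
    col2 = col.transpose(0, 4, 5, 1, 2, 3).reshape(B * ho * wo, C * kh * kw)
    wmat = w.data.reshape(O, -1)
    out_mat = col2 @ wmat.T
    if b is not None:
        out_mat += b.data
    out_data = out_mat.reshape(B, ho, wo, O).transpose(0, 3, 1, 2)

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._make(out_data, parents)
    if out.requires_grad:
        def _backward():
            g = out.grad.transpose(0, 2, 3, 1).reshape(B * ho * wo, O)
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=0))
            if w.requires_grad:
                w._accumulate((g.T @ col2).reshape(w.shape))
            if x.requires_grad:
                dcol = (g @ wmat).reshape(B, ho, wo, C, kh, kw).transpose(0, 3, 4, 5, 1, 2)
                hp, wp = H + 2 * padding, W + 2 * padding
                dxp = np.zeros((B, C, hp, wp), dtype=np.float32)
                for i in range(kh):
                    i_end = i + ho * stride
                    for j in range(kw):
                        j_end = j + wo * stride
                        dxp[:, :, i:i_end:stride, j:j_end:stride] += dcol[:, :, i, j]
                if padding:
                    dxp = dxp[:, :, padding:hp - padding, padding:wp - padding]
                x._accumulate(dxp)
        out._backward = _backward
    return out


def max_pool2d(x: Tensor, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    B, C, H, W = x.shape
    ho = (H + 2 * padding - kernel) // stride + 1
    wo = (W + 2 * padding - kernel) // stride + 1
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    col = _im2col(xp, kernel, kernel, stride, ho, wo)
    col = col.reshape(B, C, kernel * kernel, ho, wo)
    arg = col.argmax(axis=2)
    out_data = np.take_along_axis(col, arg[:, :, None], axis=2)[:, :, 0]
    out = Tensor._make(out_data, (x,))
    if out.requires_grad:
        def _backward():
            hp, wp = H + 2 * padding, W + 2 * padding
            dxp = np.zeros((B, C, hp, wp), dtype=np.float32)
            for k in range(kernel * kernel):
                i, j = divmod(k, kernel)
                mask = (arg == k)
                if not mask.any():
                    continue
                contrib = np.where(mask, out.grad, 0.0)
                dxp[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += contrib
            if padding:
                dxp = dxp[:, :, padding:hp - padding, padding:wp - padding]
            x._accumulate(dxp)
        out._backward = _backward
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    B, C, H, W = x.shape
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = Tensor._make(out_data, (x,))
    if out.requires_grad:
        def _backward():
            g = out.grad.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5))
            x._accumulate(g)
        out._backward = _backward
    return out


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.03,
                 eps: float = 1e-3) -> Tensor:
    """Channelwise batch normalization with affine parameters.

    Running statistics are numpy buffers updated in place during training
    (exponential moving average, unbiased variance, stock detector settings
    momentum=0.03 / eps=1e-3).
    """
    B, C, H, W = x.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        n = B * H * W
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[:, None, None]) * inv_std[:, None, None]
    out_data = gamma.data[:, None, None] * xhat + beta.data[:, None, None]
    out = Tensor._make(out_data, (x, gamma, beta))
    if out.requires_grad:
        def _backward():
            g = out.grad
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=(0, 2, 3)))
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gs = gamma.data[:, None, None] * inv_std[:, None, None]
                if training:
                    m = float(B * H * W)
                    mean_g = g.mean(axis=(0, 2, 3), keepdims=True)
                    mean_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
                    dx = gs * (g - mean_g - xhat * mean_gx)
                else:
                    dx = gs * g
                x._accumulate(dx.astype(np.float32))
        out._backward = _backward
    return out
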