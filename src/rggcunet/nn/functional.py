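"""Differentiable array primitives for convolutional encoder-decoders.

All functions take and return :class:`~rggcunet.nn.tensor.Tensor` and build
the autodiff tape.  Convolutions are evaluated through BLAS where possible
(pointwise tensordot, im2col matmul) and through grouped einsum for
depthwise kernels.  Each primitive reports its analytic multiply-accumulate
count to the active :class:`~rggcunet.nn.profile.MacCounter`.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import profile
from .tensor import Tensor

__all__ = [
    "conv2d", "conv_transpose2d", "batch_norm2d", "max_pool2d",
    "bilinear_resize", "softmax",
]


def _pair(v):
    return (v, v) if np.isscalar(v) else tuple(v)


def _strided_patches(xd: np.ndarray, kh: int, kw: int, sh: int, sw: int,
                     ph: int, pw: int):
    """Zero-pad and extract (N, C, Ho, Wo, kh, kw) convolution patches."""
    if ph or pw:
        xd = np.pad(xd, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    view = sliding_window_view(xd, (kh, kw), axis=(2, 3))
    return xd, view[:, :, ::sh, ::sw]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, padding=0,
           groups: int = 1) -> Tensor:
    """Grouped 2D cross-correlation; ``w`` has shape (O, C//groups, kh, kw)."""
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    O, Cg, kh, kw = wd.shape
    if C != Cg * groups or O % groups:
        raise ValueError(
            f"conv2d channel mismatch: input {C}, weight {wd.shape}, groups {groups}")
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1

    pointwise = kh == 1 and kw == 1 and groups == 1
    cols = None
    if pointwise:
        xs = xd[:, :, ::sh, ::sw] if (sh > 1 or sw > 1) else xd
        if ph or pw:  # 1x1 with padding is unusual; fall through to im2col
            pointwise = False
        else:
            out = np.tensordot(xs, wd[:, :, 0, 0], axes=([1], [1]))  # N,Ho,Wo,O
            out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    if not pointwise:
        _, view = _strided_patches(xd, kh, kw, sh, sw, ph, pw)
        if groups == 1:
            cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)).reshape(
                N * Ho * Wo, C * kh * kw)
            out = (cols @ wd.reshape(O, -1).T).reshape(N, Ho, Wo, O)
            out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
        else:
            vg = view.reshape(N, groups, C // groups, Ho, Wo, kh, kw)
            wg = wd.reshape(groups, O // groups, C // groups, kh, kw)
            out = np.einsum("ngchwkl,gockl->ngohw", vg, wg, optimize=True)
            out = out.reshape(N, O, Ho, Wo)
    if b is not None:
        out = out + b.data[None, :, None, None]

    profile.add_macs(N * Ho * Wo * O * (C // groups) * kh * kw
                     + (N * Ho * Wo * O if b is not None else 0))

    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            if pointwise:
                xs_ = xd[:, :, ::sh, ::sw] if (sh > 1 or sw > 1) else xd
                dw = np.tensordot(g, xs_, axes=([0, 2, 3], [0, 2, 3]))  # O,C
                w._accumulate(dw.reshape(wd.shape))
            elif groups == 1:
                g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(
                    N * Ho * Wo, O)
                w._accumulate((g2.T @ cols).reshape(wd.shape))
            else:
                _, view_ = _strided_patches(xd, kh, kw, sh, sw, ph, pw)
                vg_ = view_.reshape(N, groups, C // groups, Ho, Wo, kh, kw)
                dyg = g.reshape(N, groups, O // groups, Ho, Wo)
                dw = np.einsum("ngohw,ngchwkl->gockl", dyg, vg_, optimize=True)
                w._accumulate(dw.reshape(wd.shape))
        if x.requires_grad:
            Hp, Wp = H + 2 * ph, W + 2 * pw
            dxp = np.zeros((N, C, Hp, Wp), dtype=xd.dtype)
            if groups == 1:
                for k in range(kh):
                    for l in range(kw):
                        contrib = np.tensordot(g, wd[:, :, k, l], axes=([1], [0]))
                        contrib = contrib.transpose(0, 3, 1, 2)  # N,C,Ho,Wo
                        dxp[:, :, k:k + Ho * sh:sh, l:l + Wo * sw:sw] += contrib
            else:
                wg_ = wd.reshape(groups, O // groups, C // groups, kh, kw)
                dyg = g.reshape(N, groups, O // groups, Ho, Wo)
                for k in range(kh):
                    for l in range(kw):
                        contrib = np.einsum("ngohw,goc->ngchw", dyg,
                                            wg_[:, :, :, k, l], optimize=True)
                        contrib = contrib.reshape(N, C, Ho, Wo)
                        dxp[:, :, k:k + Ho * sh:sh, l:l + Wo * sw:sw] += contrib
            x._accumulate(dxp[:, :, ph:ph + H, pw:pw + W])

    return Tensor(out, req, parents, bwd if req else None)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2) -> Tensor:
    """Transposed convolution with kernel == stride (exact upsampling tiling).

    ``w`` has shape (C_in, O, k, k); output is (N, O, H*k, W*k).
    """
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    Cw, O, k, k2 = wd.shape
    if Cw != C or k != k2 or k != stride:
        raise ValueError("conv_transpose2d requires weight (C,O,k,k) with k == stride")
    t = np.einsum("nchw,cokl->nohwkl", xd, wd, optimize=True)
    out = np.ascontiguousarray(t.transpose(0, 1, 2, 4, 3, 5)).reshape(
        N, O, H * k, W * k)
    if b is not None:
        out = out + b.data[None, :, None, None]
    profile.add_macs(N * H * W * C * O * k * k
                     + (N * H * k * W * k * O if b is not None else 0))

    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        dt = g.reshape(N, O, H, k, W, k).transpose(0, 1, 2, 4, 3, 5)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accumulate(np.einsum("nohwkl,nchw->cokl", dt, xd, optimize=True))
        if x.requires_grad:
            x._accumulate(np.einsum("nohwkl,cokl->nchw", dt, wd, optimize=True))

    return Tensor(out, req, parents, bwd if req else None)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation with affine transform.

    Running statistics are plain arrays updated in place during training
    (biased variance, exponential moving average with ``momentum``).
    """
    xd = x.data
    N, C, H, W = xd.shape
    if training:
        m = xd.mean(axis=(0, 2, 3))
        v = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * m
        running_var *= 1.0 - momentum
        running_var += momentum * v
    else:
        m, v = running_mean, running_var
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (xd - m[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    profile.add_macs(N * C * H * W)

    req = x.requires_grad or gamma.requires_grad or beta.requires_grad

    def bwd(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            ginv = (gamma.data * inv)[None, :, None, None]
            if training:
                M = N * H * W
                dxhat = g * gamma.data[None, :, None, None]
                s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (dxhat - s1 / M - xhat * s2 / M) * inv[None, :, None, None]
                x._accumulate(dx)
            else:
                x._accumulate(g * ginv)

    return Tensor(out, req, (x, gamma, beta), bwd if req else None)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2,
               padding: int = 1) -> Tensor:
    xd = x.data
    N, C, H, W = xd.shape
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    Hp, Wp = xp.shape[2:]
    view = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride,
                                                                  ::stride]
    N_, C_, Ho, Wo = view.shape[:4]
    win = view.reshape(N, C, Ho, Wo, kernel * kernel)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    req = x.requires_grad

    def bwd(g):
        dxp = np.zeros((N, C, Hp, Wp), dtype=xd.dtype)
        ii = np.arange(Ho)[None, None, :, None] * stride + idx // kernel
        jj = np.arange(Wo)[None, None, None, :] * stride + idx % kernel
        nn = np.arange(N)[:, None, None, None]
        cc = np.arange(C)[None, :, None, None]
        flat = ((nn * C + cc) * Hp + ii) * Wp + jj
        np.add.at(dxp.reshape(-1), flat.ravel(), g.ravel())
        x._accumulate(dxp[:, :, padding:padding + H, padding:padding + W])

    return Tensor(out, req, (x,), bwd if req else None)


def _resize_axis_weights(n_in: int, n_out: int):
    """Half-pixel-centre (align_corners=False) bilinear sampling weights."""
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(np.intp)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = src - i0
    return i0, i1, 1.0 - w1, w1


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear resampling with half-pixel centres."""
    xd = x.data
    N, C, H, W = xd.shape
    r0, r1, wr0, wr1 = _resize_axis_weights(H, out_h)
    c0, c1, wc0, wc1 = _resize_axis_weights(W, out_w)
    rows = xd[:, :, r0, :] * wr0[None, None, :, None] \
        + xd[:, :, r1, :] * wr1[None, None, :, None]
    out = rows[:, :, :, c0] * wc0[None, None, None, :] \
        + rows[:, :, :, c1] * wc1[None, None, None, :]
    profile.add_macs(4 * N * C * out_h * out_w)
    req = x.requires_grad

    def bwd(g):
        drows = np.zeros((N, C, out_h, W), dtype=xd.dtype)
        gc = np.moveaxis(g, 3, 0)           # (out_w, N, C, out_h)
        drT = np.moveaxis(drows, 3, 0)      # (W, N, C, out_h) view
        np.add.at(drT, c0, gc * wc0[:, None, None, None])
        np.add.at(drT, c1, gc * wc1[:, None, None, None])
        dx = np.zeros_like(xd)
        gr = np.moveaxis(drows, 2, 0)       # (out_h, N, C, W)
        dxT = np.moveaxis(dx, 2, 0)         # (H, N, C, W) view
        np.add.at(dxT, r0, gr * wr0[:, None, None, None])
        np.add.at(dxT, r1, gr * wr1[:, None, None, None])
        x._accumulate(dx)

    return Tensor(out, req, (x,), bwd if req else None)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    xd = x.data
    e = np.exp(xd - xd.max(axis=axis, keepdims=True))
    out = e / e.sum(axis=axis, keepdims=True)
    req = x.requires_grad

    def bwd(g):
        inner = (g * out).sum(axis=axis, keepdims=True)
        x._accumulate(out * (g - inner))

    return Tensor(out, req, (x,), bwd if req else None)
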