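"""Spatial neural-network primitives (stride-1 convolutions, non-overlapping
transposed convolutions and pooling, and a differentiable affine warp).

Convolutions are evaluated by unrolling sliding windows into a matrix
product; their adjoints scatter gradients back window-by-window (k*k
additions, cheap for the 3x3 kernels used here).  The affine warp follows
the spatial-transformer convention: a 2x3 matrix maps *output* grid
coordinates, normalized to [-1, 1] with corners aligned, to input
coordinates, which are sampled bilinearly with zeros outside the image.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor

__all__ = [
    "conv2d",
    "conv3d",
    "conv_transpose2d",
    "conv_transpose3d",
    "maxpool2d",
    "avgpool2d",
    "affine_warp",
]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, padding: int = 1) -> Tensor:
    """``x``: (N,C,H,W), ``w``: (F,C,k,k), stride 1. Output (N,F,H',W')."""
    n, c, _, _ = x.shape
    f, cw, k, _ = w.shape
    if cw != c:
        raise ValueError(f"conv2d channel mismatch: input has {c}, weight expects {cw}")
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    ho = xp.shape[2] - k + 1
    wo = xp.shape[3] - k + 1
    hw = ho * wo
    # shift-and-matmul: one batched GEMM per kernel tap keeps copies small
    shifts: list[np.ndarray] = []
    acc = None
    for i in range(k):
        for j in range(k):
            xs = np.ascontiguousarray(xp[:, :, i : i + ho, j : j + wo]).reshape(n, c, hw)
            shifts.append(xs)
            r = np.matmul(w.data[:, :, i, j], xs)  # (F,C)@(N,C,HW) -> (N,F,HW)
            acc = r if acc is None else acc + r
    if b is not None:
        acc += b.data[:, None]
    out = acc.reshape(n, f, ho, wo)

    def backward(g):
        gt = g.reshape(n, f, hw)
        if b is not None and b.requires_grad:
            b._accumulate(gt.sum(axis=(0, 2)))
        dw = np.zeros_like(w.data) if w.requires_grad else None
        dxp = np.zeros_like(xp) if x.requires_grad else None
        for idx in range(k * k):
            i, j = divmod(idx, k)
            if dw is not None:
                dw[:, :, i, j] = np.tensordot(gt, shifts[idx], axes=([0, 2], [0, 2]))
            if dxp is not None:
                dxs = np.matmul(w.data[:, :, i, j].T, gt)  # (N,C,HW)
                dxp[:, :, i : i + ho, j : j + wo] += dxs.reshape(n, c, ho, wo)
        if dw is not None:
            w._accumulate(dw)
        if dxp is not None:
            x._accumulate(dxp[:, :, padding : padding + x.shape[2], padding : padding + x.shape[3]]
                          if padding else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, padding: int = 1) -> Tensor:
    """``x``: (N,C,D,H,W), ``w``: (F,C,k,k,k), stride 1."""
    n, c, _, _, _ = x.shape
    f, cw, k, _, _ = w.shape
    if cw != c:
        raise ValueError(f"conv3d channel mismatch: input has {c}, weight expects {cw}")
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))  # (N,C,Do,Ho,Wo,k,k,k)
    do, ho, wo = win.shape[2:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n, do, ho, wo, c * k**3)
    wmat = w.data.reshape(f, -1)
    out = cols @ wmat.T
    if b is not None:
        out = out + b.data
    out = np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))

    def backward(g):
        gt = g.transpose(0, 2, 3, 4, 1)
        if w.requires_grad:
            w._accumulate((gt.reshape(-1, f).T @ cols.reshape(-1, c * k**3)).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gt.sum(axis=(0, 1, 2, 3)))
        if x.requires_grad:
            dcols = (gt @ wmat).reshape(n, do, ho, wo, c, k, k, k)
            dxp = np.zeros_like(xp)
            for a in range(k):
                for i in range(k):
                    for j in range(k):
                        dxp[:, :, a : a + do, i : i + ho, j : j + wo] += dcols[
                            :, :, :, :, :, a, i, j
                        ].transpose(0, 4, 1, 2, 3)
            if p:
                dxp = dxp[:, :, p:-p, p:-p, p:-p]
            x._accumulate(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, kernel: int = 2) -> Tensor:
    """Transposed convolution with kernel == stride (non-overlapping).

    ``x``: (N,C,H,W), ``w``: (C,F,k,k) -> output (N,F,k*H,k*W).
    """
    n, c, h, wd = x.shape
    _, f, k, _ = w.shape
    # (n,h,wd,f,a,b) -> (n,f,h,a,wd,b)
    out = np.tensordot(x.data, w.data, axes=([1], [0])).transpose(0, 3, 1, 4, 2, 5)
    out = out.reshape(n, f, h * k, wd * k)
    if b is not None:
        out = out + b.data[:, None, None]

    def backward(g):
        g6 = g.reshape(n, f, h, k, wd, k).transpose(0, 2, 4, 1, 3, 5)  # (n,h,wd,f,a,b)
        if x.requires_grad:
            x._accumulate(
                np.tensordot(g6, w.data, axes=([3, 4, 5], [1, 2, 3])).transpose(0, 3, 1, 2)
            )
        if w.requires_grad:
            w._accumulate(np.tensordot(x.data, g6, axes=([0, 2, 3], [0, 1, 2])))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(np.ascontiguousarray(out), parents, backward)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None, kernel: tuple[int, int, int] = (1, 2, 2)) -> Tensor:
    """Transposed convolution with kernel == stride, per-axis kernel sizes.

    ``x``: (N,C,D,H,W), ``w``: (C,F,kd,kh,kw).
    """
    n, c, d, h, wd = x.shape
    _, f, kd, kh, kw = w.shape
    out = np.einsum("ncdhw,cfqab->nfdqhawb", x.data, w.data).reshape(n, f, d * kd, h * kh, wd * kw)
    if b is not None:
        out = out + b.data[:, None, None, None]

    def backward(g):
        g8 = g.reshape(n, f, d, kd, h, kh, wd, kw)
        if x.requires_grad:
            x._accumulate(np.einsum("nfdqhawb,cfqab->ncdhw", g8, w.data))
        if w.requires_grad:
            w._accumulate(np.einsum("nfdqhawb,ncdhw->cfqab", g8, x.data))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(np.ascontiguousarray(out), parents, backward)


def _pool_view(x: np.ndarray, k: int):
    n, c, h, w = x.shape
    return x.reshape(n, c, h // k, k, w // k, k).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, h // k, w // k, k * k
    )


def maxpool2d(x: Tensor, k: int = 2) -> Tensor:
    """Max pooling over non-overlapping k x k windows (last two axes).

    Works on (..., H, W); gradients flow to the first arg-max of each window.
    """
    lead = x.shape[:-2]
    h, w = x.shape[-2:]
    if h % k or w % k:
        raise ValueError(f"maxpool2d: spatial extent {(h, w)} not divisible by {k}")
    win = x.data.reshape(*lead, h // k, k, w // k, k)
    win = np.moveaxis(win, -3, -2).reshape(*lead, h // k, w // k, k * k)
    idx = np.argmax(win, axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dwin = np.zeros((*lead, h // k, w // k, k * k), dtype=x.data.dtype)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dwin = dwin.reshape(*lead, h // k, w // k, k, k)
        dwin = np.moveaxis(dwin, -2, -3).reshape(*lead, h, w)
        x._accumulate(dwin)

    return Tensor._make(np.ascontiguousarray(out), (x,), backward)


def avgpool2d(x: Tensor, k: int = 2) -> Tensor:
    """Average pooling over non-overlapping k x k windows (last two axes)."""
    lead = x.shape[:-2]
    h, w = x.shape[-2:]
    if h % k or w % k:
        raise ValueError(f"avgpool2d: spatial extent {(h, w)} not divisible by {k}")
    win = x.data.reshape(*lead, h // k, k, w // k, k)
    out = win.mean(axis=(-3, -1))

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.repeat(np.repeat(g, k, axis=-2), k, axis=-1) / (k * k))

    return Tensor._make(np.ascontiguousarray(out), (x,), backward)


_GRID_CACHE: dict[tuple, np.ndarray] = {}


def _base_grid(h: int, w: int, dtype) -> np.ndarray:
    """Homogeneous normalized output coordinates, rows (xn, yn, 1), (3,HW)."""
    key = (h, w, np.dtype(dtype).str)
    if key not in _GRID_CACHE:
        yn = np.linspace(-1.0, 1.0, h, dtype=dtype) if h > 1 else np.zeros(1, dtype=dtype)
        xn = np.linspace(-1.0, 1.0, w, dtype=dtype) if w > 1 else np.zeros(1, dtype=dtype)
        gy, gx = np.meshgrid(yn, xn, indexing="ij")
        _GRID_CACHE[key] = np.stack([gx.ravel(), gy.ravel(), np.ones(h * w, dtype=dtype)])
    return _GRID_CACHE[key]


def affine_warp(x: Tensor, theta: Tensor) -> Tensor:
    """Warp feature maps by a 2x3 affine acting on normalized coordinates.

    ``x``: (N,C,H,W); ``theta``: (N,2,3).  Row 0 of theta produces the
    source x-coordinate, row 1 the source y-coordinate; both input and
    output grids span [-1, 1] with corners aligned.  Samples falling
    outside the input are zero.  Differentiable in both arguments.
    """
    n, c, h, w = x.shape
    base = _base_grid(h, w, x.data.dtype)  # (3,HW)
    src = theta.data @ base  # (N,2,HW): row 0 = xs, row 1 = ys
    jx = (src[:, 0] + 1.0) * (w - 1) / 2.0  # fractional column index
    iy = (src[:, 1] + 1.0) * (h - 1) / 2.0

    j0 = np.floor(jx).astype(np.int64)
    i0 = np.floor(iy).astype(np.int64)
    fj = (jx - j0).astype(x.data.dtype)
    fi = (iy - i0).astype(x.data.dtype)

    xflat = x.data.reshape(n, c, h * w)
    bidx = np.arange(n)[:, None]  # (N,1) batch index for gathers
    out = np.zeros((n, c, h * w), dtype=x.data.dtype)
    corners = []
    for di, dj, wt in (
        (0, 0, (1 - fi) * (1 - fj)),
        (0, 1, (1 - fi) * fj),
        (1, 0, fi * (1 - fj)),
        (1, 1, fi * fj),
    ):
        ii, jj = i0 + di, j0 + dj
        valid = (ii >= 0) & (ii < h) & (jj >= 0) & (jj < w)
        flat = np.clip(ii, 0, h - 1) * w + np.clip(jj, 0, w - 1)  # (N,HW)
        vals = xflat[bidx, :, flat].swapaxes(1, 2)  # (N,C,HW)
        vw = wt * valid
        out += vals * vw[:, None, :]
        corners.append((di, dj, flat, valid, vw, vals))

    def backward(g):
        gf = g.reshape(n, c, h * w)
        if x.requires_grad:
            dx = np.zeros(n * c * h * w, dtype=x.data.dtype)
            for _, _, flat, _, vw, _ in corners:
                contrib = (gf * vw[:, None, :]).ravel()
                idx = (
                    np.arange(n * c)[:, None] * (h * w)
                    + np.repeat(flat, c, axis=0).reshape(n * c, h * w)
                ).ravel()
                dx += np.bincount(idx, weights=contrib, minlength=dx.size).astype(x.data.dtype)
            x._accumulate(dx.reshape(x.shape))
        if theta.requires_grad:
            djx = np.zeros((n, h * w), dtype=x.data.dtype)
            diy = np.zeros((n, h * w), dtype=x.data.dtype)
            for di, dj, flat, valid, vw, vals in corners:
                gv = (gf * vals).sum(axis=1) * valid  # (N,HW)
                wi = (1 - fi) if di == 0 else fi
                wj = (1 - fj) if dj == 0 else fj
                dwj = -1.0 if dj == 0 else 1.0
                dwi = -1.0 if di == 0 else 1.0
                djx += gv * wi * dwj
                diy += gv * wj * dwi
            dxs = djx * (w - 1) / 2.0
            dys = diy * (h - 1) / 2.0
            dsrc = np.stack([dxs, dys], axis=1)  # (N,2,HW)
            theta._accumulate(dsrc @ base.T)

    return Tensor._make(out.reshape(n, c, h, w), (x, theta), backward)
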