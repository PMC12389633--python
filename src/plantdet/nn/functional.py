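"""Convolution, pooling and loss primitives with custom backward passes.

Convolution is im2col + matmul; its backward scatters column gradients
back with a kh*kw loop (cheap for the 1x1/3x3/7x7 kernels used here).
"""
from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "conv2d",
    "max_pool2d",
    "roi_max_pool",
    "log_softmax",
    "cross_entropy",
    "smooth_l1",
    "bce_with_logits",
]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    """x already padded, (N,C,H,W) -> (N, C, kh, kw, Ho, Wo) view-copy."""
    n, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return np.ascontiguousarray(view), ho, wo


def _col2im(dcols: np.ndarray, padded_shape, kh, kw, stride):
    n, c, h, w = padded_shape
    ho, wo = dcols.shape[4], dcols.shape[5]
    dx = np.zeros(padded_shape, dtype=np.float32)
    for i in range(kh):
        hi = i + (ho - 1) * stride + 1
        for j in range(kw):
            wj = j + (wo - 1) * stride + 1
            dx[:, :, i:hi:stride, j:wj:stride] += dcols[:, :, i, j]
    return dx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """NCHW convolution. weight: (Cout, Cin/groups, kh, kw)."""
    n, c, h, w = x.shape
    cout, cin_g, kh, kw = weight.shape
    if c != cin_g * groups:
        raise ValueError(
            f"conv2d channel mismatch: input has {c} channels, "
            f"weight expects {cin_g * groups} (groups={groups})"
        )
    if cout % groups:
        raise ValueError(f"out channels {cout} not divisible by groups {groups}")
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols, ho, wo = _im2col(xp, kh, kw, stride)          # (N,C,kh,kw,Ho,Wo)
    g = groups
    cpg, opg = c // g, cout // g
    colsg = cols.reshape(n, g, cpg * kh * kw, ho * wo)
    wg = weight.data.reshape(g, opg, cpg * kh * kw)
    out = np.einsum("gok,ngkl->ngol", wg, colsg, optimize=True)
    out = out.reshape(n, cout, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(gout):
        gflat = gout.reshape(n, g, opg, ho * wo)
        if weight.requires_grad:
            gw = np.einsum("ngol,ngkl->gok", gflat, colsg, optimize=True)
            weight._accum(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(gout.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcolsg = np.einsum("gok,ngol->ngkl", wg, gflat, optimize=True)
            dcols = dcolsg.reshape(n, c, kh, kw, ho, wo)
            dxp = _col2im(dcols, xp.shape, kh, kw, stride)
            if padding:
                dxp = dxp[:, :, padding:padding + h, padding:padding + w]
            x._accum(dxp)

    return Tensor._make(out, parents, backward)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    n, c, h, w = x.shape
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    cols, ho, wo = _im2col(xp, kernel, kernel, stride)
    flat = cols.reshape(n, c, kernel * kernel, ho, wo)
    arg = flat.argmax(axis=2)
    out = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        if not x.requires_grad:
            return
        dcols = np.zeros_like(flat)
        np.put_along_axis(dcols, arg[:, :, None], g[:, :, None], axis=2)
        dxp = _col2im(dcols.reshape(n, c, kernel, kernel, ho, wo),
                      xp.shape, kernel, kernel, stride)
        if padding:
            dxp = dxp[:, :, padding:padding + h, padding:padding + w]
        x._accum(dxp)

    return Tensor._make(out, (x,), backward)


def roi_max_pool(features: Tensor, rois: np.ndarray, output_size: int,
                 spatial_scale: float = 1.0) -> Tensor:
    """Max-pool each RoI into an output_size x output_size grid.

    features: (1, C, H, W); rois: (R, 4) boxes in input pixels, half-open.
    Empty bins are clamped to at least one cell.
    """
    if features.shape[0] != 1:
        raise ValueError("roi_max_pool expects batch size 1")
    _, c, h, w = features.shape
    r = len(rois)
    p = output_size
    out = np.zeros((r, c, p, p), dtype=np.float32)
    # flat spatial argmax per (roi, bin) for the backward scatter
    argmax = np.zeros((r, c, p, p), dtype=np.int64)
    fmap = features.data[0].reshape(c, -1)
    for ri, (x1, y1, x2, y2) in enumerate(rois):
        x1 = int(np.floor(x1 * spatial_scale))
        y1 = int(np.floor(y1 * spatial_scale))
        x2 = int(np.ceil(x2 * spatial_scale))
        y2 = int(np.ceil(y2 * spatial_scale))
        x1 = min(max(x1, 0), w - 1)
        y1 = min(max(y1, 0), h - 1)
        x2 = min(max(x2, x1 + 1), w)
        y2 = min(max(y2, y1 + 1), h)
        bh = (y2 - y1) / p
        bw = (x2 - x1) / p
        for i in range(p):
            ys = y1 + int(np.floor(i * bh))
            ye = y1 + max(int(np.ceil((i + 1) * bh)), int(np.floor(i * bh)) + 1)
            ye = min(ye, y2)
            for j in range(p):
                xs = x1 + int(np.floor(j * bw))
                xe = x1 + max(int(np.ceil((j + 1) * bw)), int(np.floor(j * bw)) + 1)
                xe = min(xe, x2)
                patch = features.data[0, :, ys:ye, xs:xe].reshape(c, -1)
                a = patch.argmax(axis=1)
                rows = a // (xe - xs) + ys
                colsj = a % (xe - xs) + xs
                flat = rows * w + colsj
                out[ri, :, i, j] = fmap[np.arange(c), flat]
                argmax[ri, :, i, j] = flat

    def backward(g):
        if not features.requires_grad:
            return
        dflat = np.zeros((c, h * w), dtype=np.float32)
        ch_idx = np.broadcast_to(np.arange(c)[None, :, None, None], argmax.shape)
        np.add.at(dflat, (ch_idx.ravel(), argmax.ravel()), g.ravel())
        features._accum(dflat.reshape(1, c, h, w))

    return Tensor._make(out, (features,), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, mean=None, var=None,
               eps: float = 1e-5):
    """Fused batch normalization over (N, H, W) per channel.

    With mean/var given (eval mode) they are treated as constants;
    otherwise batch statistics are used and differentiated through.
    Returns (out, batch_mean, batch_var) - the stats as plain arrays.
    """
    n, c, h, w = x.shape
    xd = x.data
    use_batch_stats = mean is None
    if use_batch_stats:
        mean = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
    mu = np.asarray(mean, dtype=np.float32).reshape(1, c, 1, 1)
    v = np.asarray(var, dtype=np.float32).reshape(1, c, 1, 1)
    inv_std = 1.0 / np.sqrt(v + eps)
    xhat = (xd - mu) * inv_std
    out = xhat * gamma.data.reshape(1, c, 1, 1) + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxh = g * gamma.data.reshape(1, c, 1, 1)
            if use_batch_stats:
                m = n * h * w
                s1 = gxh.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gxh * xhat).sum(axis=(0, 2, 3), keepdims=True)
                x._accum(inv_std * (gxh - s1 / m - xhat * s2 / m))
            else:
                x._accum(gxh * inv_std)

    out_t = Tensor._make(out, (x, gamma, beta), backward)
    return out_t, np.asarray(mean), np.asarray(var)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood; labels are integer class ids."""
    lsm = log_softmax(logits, axis=-1)
    n = logits.shape[0]
    picked = lsm[(np.arange(n), np.asarray(labels))]
    return -picked.mean()


def smooth_l1(pred: Tensor, target: np.ndarray, beta: float = 1.0) -> Tensor:
    """Mean smooth-L1 (Huber) over all elements."""
    diff = pred - Tensor(target)
    ad = np.abs(diff.data)
    quad = ad < beta
    # branch masks are constants w.r.t. the graph
    q = Tensor(quad.astype(np.float32))
    l2 = diff * diff * (0.5 / beta)
    l1 = diff * Tensor(np.sign(diff.data)) - 0.5 * beta
    return (q * l2 + (1.0 - q) * l1).mean()


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits, numerically stable."""
    t = Tensor(np.asarray(targets, dtype=np.float32))
    x = logits
    # max(x,0) - x*t + log(1+exp(-|x|)), all built from stable primitives
    relu_x = x.relu()
    abs_x = relu_x + (-x).relu()
    softplus = (1.0 + (-abs_x).exp()).log()
    return (softplus + relu_x - x * t).mean()
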