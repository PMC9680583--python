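"""Spatial primitives for the autodiff engine: padding, convolution,
instance normalisation, upsampling, location gather and the
temperature-scaled contrastive cross-entropy.

Convolution is evaluated as k x k shifted matrix products (one GEMM per
kernel tap) rather than a monolithic im2col, which keeps memory traffic
row-contiguous; the adjoint accumulates into strided views of the padded
input, so stride handling stays exact.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


def pad2d(x: Tensor, pad: int, mode: str = "constant", value: float = 0.0) -> Tensor:
    """Pad the two trailing (spatial) axes of an NCHW tensor."""
    if pad == 0:
        return x
    widths = ((0, 0), (0, 0), (pad, pad), (pad, pad))
    if mode == "constant":
        data = np.pad(x.data, widths, mode="constant", constant_values=value)
        out = Tensor(data, parents=(x,))
        if out.requires_grad:
            def backward(g, a=x, p=pad):
                Tensor._accum(a, g[:, :, p:-p, p:-p])
            out._backward = backward
        return out
    if mode == "reflect":
        data = np.pad(x.data, widths, mode="reflect")
        out = Tensor(data, parents=(x,))
        if out.requires_grad:
            h, w = x.shape[2], x.shape[3]
            sidx = np.pad(np.arange(h * w, dtype=np.int64).reshape(h, w),
                          pad, mode="reflect").ravel()
            def backward(g, a=x, sidx=sidx, h=h, w=w):
                n, c = g.shape[0], g.shape[1]
                gf = g.reshape(n * c, -1)
                dx = np.empty((n * c, h * w), dtype=g.dtype)
                for i in range(n * c):
                    dx[i] = np.bincount(sidx, weights=gf[i], minlength=h * w)
                Tensor._accum(a, dx.reshape(a.data.shape))
            out._backward = backward
        return out
    raise ValueError(f"unknown pad mode: {mode!r}")


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1) -> Tensor:
    """2D convolution (cross-correlation) of a padded NCHW input.

    ``weight`` is (OC, C, k, k); padding is applied by the caller via
    :func:`pad2d` so both zero and reflect conventions share one kernel.
    """
    oc, c, k, _ = weight.shape
    n, cx, h, w = x.shape
    if cx != c:
        raise ValueError(f"channel mismatch: input {cx}, weight {c}")
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"input {h}x{w} smaller than kernel {k}")
    xd = x.data
    L = ho * wo
    # im2col assembled tap-by-tap with row-contiguous copies, then one GEMM;
    # column ordering is (tap, channel) so the weight is reordered to match
    cols = np.empty((n, k * k * c, L), dtype=xd.dtype)
    for t, (i, j) in enumerate((i, j) for i in range(k) for j in range(k)):
        xs = xd[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride]
        cols[:, t * c:(t + 1) * c, :] = xs.reshape(n, c, L)
    wm = np.ascontiguousarray(
        weight.data.transpose(2, 3, 1, 0).reshape(k * k * c, oc).T)
    out_data = (np.matmul(wm, cols)
                + bias.data.reshape(1, oc, 1)).reshape(n, oc, ho, wo)
    out = Tensor(out_data, parents=(x, weight, bias))
    if out.requires_grad:
        def backward(g, x=x, weight=weight, bias=bias, cols=cols,
                     wm=wm, k=k, c=c, stride=stride, ho=ho, wo=wo):
            n, oc = g.shape[0], g.shape[1]
            gm = np.ascontiguousarray(g).reshape(n, oc, ho * wo)
            if bias.requires_grad:
                Tensor._accum(bias, gm.sum(axis=(0, 2)))
            if weight.requires_grad:
                dwm = np.matmul(gm, cols.transpose(0, 2, 1)).sum(axis=0)
                Tensor._accum(weight, dwm.reshape(oc, k, k, c)
                              .transpose(0, 3, 1, 2))
            if x.requires_grad:
                dcols = np.matmul(wm.T, gm)        # (n, k*k*c, L)
                dx = np.zeros_like(x.data)
                for t, (i, j) in enumerate((i, j) for i in range(k)
                                           for j in range(k)):
                    dx[:, :, i:i + stride * ho:stride,
                       j:j + stride * wo:stride] += dcols[
                           :, t * c:(t + 1) * c, :].reshape(n, c, ho, wo)
                Tensor._accum(x, dx)
        out._backward = backward
    return out


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                  eps: float = 1e-5) -> Tensor:
    """Fused per-sample, per-channel normalisation over the spatial axes
    with affine parameters of shape (1, C, 1, 1)."""
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(gamma.data * xhat + beta.data, parents=(x, gamma, beta))
    if out.requires_grad:
        def backward(g, x=x, gamma=gamma, beta=beta, xhat=xhat, inv=inv):
            if beta.requires_grad:
                Tensor._accum(beta, g.sum(axis=(0, 2, 3), keepdims=True))
            if gamma.requires_grad:
                Tensor._accum(gamma, (g * xhat).sum(axis=(0, 2, 3), keepdims=True))
            if x.requires_grad:
                gmean = g.mean(axis=(2, 3), keepdims=True)
                gxmean = (g * xhat).mean(axis=(2, 3), keepdims=True)
                Tensor._accum(x, gamma.data * inv * (g - gmean - xhat * gxmean))
        out._backward = backward
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    data = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = Tensor(data, parents=(x,))
    if out.requires_grad:
        def backward(g, a=x):
            n, c, h2, w2 = g.shape
            Tensor._accum(a, g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))
        out._backward = backward
    return out


def gather_locations(x: Tensor, flat_idx: np.ndarray) -> Tensor:
    """Pick feature vectors at flattened spatial locations.

    ``x`` is (1, C, H, W); returns (S, C), one row per sampled location.
    Locations must be distinct (they are sampled without replacement).
    """
    if x.shape[0] != 1:
        raise ValueError("gather_locations expects batch size 1")
    c = x.shape[1]
    flat = x.data.reshape(c, -1)
    out = Tensor(flat[:, flat_idx].T, parents=(x,))
    if out.requires_grad:
        def backward(g, a=x, flat_idx=flat_idx, c=c):
            dx = np.zeros((c, a.data.shape[2] * a.data.shape[3]), dtype=g.dtype)
            dx[:, flat_idx] = g.T
            Tensor._accum(a, dx.reshape(a.data.shape))
        out._backward = backward
    return out


def cross_entropy_diag(logits: Tensor) -> Tensor:
    """Mean softmax cross-entropy of an (S, S) logit matrix whose targets
    are the diagonal (row s's positive is column s).  Log-sum-exp stable.
    """
    z = logits.data
    s = z.shape[0]
    m = z.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(z - m).sum(axis=1))
    loss = np.asarray(np.mean(lse - np.diag(z)), dtype=z.dtype)
    out = Tensor(loss, parents=(logits,))
    if out.requires_grad:
        softmax = np.exp(z - lse[:, None])
        def backward(g, a=logits, softmax=softmax, s=s):
            grad = (g / s) * softmax
            grad[np.arange(s), np.arange(s)] -= g / s
            Tensor._accum(a, grad)
        out._backward = backward
    return out
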