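"""Differentiable operations for the segmentation network.

Every function takes and returns :class:`~lenseg.nn.autograd.Tensor` and
registers the closures needed for reverse-mode differentiation.  Spatial
convolutions are evaluated by unrolling the (small, 3x3) kernel over offset
slices, which keeps everything vectorised in numpy without an im2col copy of
quadratic size.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor

__all__ = [
    "add",
    "relu",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "batch_norm",
    "bilinear_resize",
    "spatial_mean",
    "broadcast_spatial",
    "softmax",
    "softmax_cross_entropy",
    "soft_iou_loss",
    "weighted_sum",
]


# ---------------------------------------------------------------------------
# basic ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.shape != b.shape:
        raise ValueError(f"add: shape mismatch {a.shape} vs {b.shape}")
    return Tensor(a.data + b.data, parents=((a, lambda g: g), (b, lambda g: g)))


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    return Tensor(x.data * mask, parents=((x, lambda g: g * mask),))


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_fn(lo, hi):
        def fn(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            return g[tuple(sl)]

        return fn

    parents = [
        (t, make_fn(int(offsets[i]), int(offsets[i + 1])))
        for i, t in enumerate(tensors)
    ]
    return Tensor(data, parents=parents)


def weighted_sum(terms, weights) -> Tensor:
    """sum_i w_i * t_i over scalar tensors (used for the total loss)."""
    terms = [as_tensor(t) for t in terms]
    if len(terms) != len(weights):
        raise ValueError("weighted_sum: length mismatch")
    data = sum(w * t.data for w, t in zip(weights, terms))
    parents = [(t, (lambda w: (lambda g: g * w))(w)) for w, t in zip(weights, terms)]
    return Tensor(data, parents=parents)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _conv_forward(xd, wd, stride, padding, dilation, groups):
    """Direct grouped dilated conv, kernel unrolled over offsets."""
    n, cin, h, w = xd.shape
    cout, cin_g, kh, kw = wd.shape
    if cin_g * groups != cin:
        raise ValueError(
            f"conv2d: input channels {cin} incompatible with weight "
            f"{wd.shape} and groups={groups}"
        )
    ho = (h + 2 * padding - dilation * (kh - 1) - 1) // stride + 1
    wo = (w + 2 * padding - dilation * (kw - 1) - 1) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError("conv2d: output would be empty")
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    xg = xp.reshape(n, groups, cin_g, *xp.shape[2:])
    wg = wd.reshape(groups, cout // groups, cin_g, kh, kw)
    out = np.zeros((n, groups, cout // groups, ho, wo))
    for i in range(kh):
        for j in range(kw):
            patch = xg[
                :, :, :,
                i * dilation : i * dilation + (ho - 1) * stride + 1 : stride,
                j * dilation : j * dilation + (wo - 1) * stride + 1 : stride,
            ]
            out += np.einsum("ngchw,goc->ngohw", patch, wg[:, :, :, i, j], optimize=True)
    return out.reshape(n, cout, ho, wo)


def _conv_backward(g, xd, wd, stride, padding, dilation, groups):
    """Return (dx, dw) for the conv above; g has the output's shape."""
    n, cin, h, w = xd.shape
    cout, cin_g, kh, kw = wd.shape
    ho, wo = g.shape[2:]
    gg = g.reshape(n, groups, cout // groups, ho, wo)
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    xg = xp.reshape(n, groups, cin_g, *xp.shape[2:])
    dw = np.zeros_like(wd).reshape(groups, cout // groups, cin_g, kh, kw)
    dxp = np.zeros_like(xg)
    for i in range(kh):
        for j in range(kw):
            rows = slice(i * dilation, i * dilation + (ho - 1) * stride + 1, stride)
            cols = slice(j * dilation, j * dilation + (wo - 1) * stride + 1, stride)
            patch = xg[:, :, :, rows, cols]
            dw[:, :, :, i, j] = np.einsum("ngohw,ngchw->goc", gg, patch, optimize=True)
            wg = wd.reshape(groups, cout // groups, cin_g, kh, kw)[:, :, :, i, j]
            dxp[:, :, :, rows, cols] += np.einsum("ngohw,goc->ngchw", gg, wg, optimize=True)
    dxp = dxp.reshape(n, cin, *xp.shape[2:])
    if padding:
        dxp = dxp[:, :, padding:-padding or None, padding:-padding or None]
    return dxp, dw.reshape(cout, cin_g, kh, kw)


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
    groups: int = 1,
) -> Tensor:
    x, weight = as_tensor(x), as_tensor(weight)
    out = _conv_forward(x.data, weight.data, stride, padding, dilation, groups)
    cache: dict = {}

    def both(g):
        key = id(g)
        if cache.get("key") != key:
            cache["key"] = key
            cache["val"] = _conv_backward(
                g, x.data, weight.data, stride, padding, dilation, groups
            )
        return cache["val"]

    parents = [
        (x, lambda g: both(g)[0]),
        (weight, lambda g: both(g)[1]),
    ]
    if bias is not None:
        bias = as_tensor(bias)
        out = out + bias.data[None, :, None, None]
        parents.append((bias, lambda g: g.sum(axis=(0, 2, 3))))
    return Tensor(out, parents=parents)


def conv_transpose2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 2,
    padding: int = 1,
    output_padding: int = 1,
) -> Tensor:
    """Transposed conv; weight is (C_in, C_out, kh, kw).

    Defaults give the exact x2 upsampling used by the plain decoder
    (3x3 kernel, stride 2, padding 1, output_padding 1).
    """
    x, weight = as_tensor(x), as_tensor(weight)
    n, cin, h, w = x.shape
    cin_w, cout, kh, kw = weight.shape
    if cin_w != cin:
        raise ValueError(f"conv_transpose2d: channel mismatch {cin} vs {cin_w}")
    ho = (h - 1) * stride - 2 * padding + kh + output_padding
    wo = (w - 1) * stride - 2 * padding + kw + output_padding

    def forward(xd, wd):
        outp = np.zeros((n, cout, ho + 2 * padding, wo + 2 * padding))
        for i in range(kh):
            for j in range(kw):
                contrib = np.einsum("nchw,co->nohw", xd, wd[:, :, i, j], optimize=True)
                outp[:, :, i : i + (h - 1) * stride + 1 : stride,
                     j : j + (w - 1) * stride + 1 : stride] += contrib
        if padding:
            outp = outp[:, :, padding:-padding or None, padding:-padding or None]
        return outp

    out = forward(x.data, weight.data)

    def grad_x(g):
        gp = np.pad(g, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        dx = np.zeros_like(x.data)
        for i in range(kh):
            for j in range(kw):
                patch = gp[:, :, i : i + (h - 1) * stride + 1 : stride,
                           j : j + (w - 1) * stride + 1 : stride]
                dx += np.einsum("nohw,co->nchw", patch, weight.data[:, :, i, j], optimize=True)
        return dx

    def grad_w(g):
        gp = np.pad(g, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        dw = np.zeros_like(weight.data)
        for i in range(kh):
            for j in range(kw):
                patch = gp[:, :, i : i + (h - 1) * stride + 1 : stride,
                           j : j + (w - 1) * stride + 1 : stride]
                dw[:, :, i, j] = np.einsum("nchw,nohw->co", x.data, patch, optimize=True)
        return dw

    parents = [(x, grad_x), (weight, grad_w)]
    if bias is not None:
        bias = as_tensor(bias)
        out = out + bias.data[None, :, None, None]
        parents.append((bias, lambda g: g.sum(axis=(0, 2, 3))))
    return Tensor(out, parents=parents)


# ---------------------------------------------------------------------------
# normalisation / resampling
# ---------------------------------------------------------------------------

def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation over (N, H, W).

    ``running_mean``/``running_var`` are plain arrays updated in place during
    training and used as the statistics in eval mode.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    xd = x.data
    if training:
        mean = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        m = xd.shape[0] * xd.shape[2] * xd.shape[3]
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        unbiased = var * (m / max(m - 1, 1))
        running_var *= 1 - momentum
        running_var += momentum * unbiased
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mean[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def grad_x(g):
        gs = g * gamma.data[None, :, None, None]
        if not training:
            return gs * inv[None, :, None, None]
        m = xd.shape[0] * xd.shape[2] * xd.shape[3]
        sum_gs = gs.sum(axis=(0, 2, 3))
        sum_gs_xhat = (gs * xhat).sum(axis=(0, 2, 3))
        return (inv[None, :, None, None] / m) * (
            m * gs
            - sum_gs[None, :, None, None]
            - xhat * sum_gs_xhat[None, :, None, None]
        )

    parents = (
        (x, grad_x),
        (gamma, lambda g: (g * xhat).sum(axis=(0, 2, 3))),
        (beta, lambda g: g.sum(axis=(0, 2, 3))),
    )
    return Tensor(out, parents=parents)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D bilinear interpolation matrix, half-pixel-centre convention."""
    a = np.zeros((n_out, n_in))
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    a[np.arange(n_out), lo] += 1 - frac
    a[np.arange(n_out), hi] += frac
    return a


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Channel-wise bilinear resampling to (out_h, out_w)."""
    x = as_tensor(x)
    if out_h < 1 or out_w < 1:
        raise ValueError("bilinear_resize: target dims must be positive")
    h, w = x.shape[-2:]
    ah = _interp_matrix(out_h, h)
    aw = _interp_matrix(out_w, w)
    out = np.einsum("oh,...hw,pw->...op", ah, x.data, aw, optimize=True)
    return Tensor(out, parents=((x, lambda g: np.einsum("oh,...op,pw->...hw", ah, g, aw, optimize=True)),))


def spatial_mean(x: Tensor) -> Tensor:
    """Global average pool to (N, C, 1, 1)."""
    x = as_tensor(x)
    h, w = x.shape[-2:]
    out = x.data.mean(axis=(-2, -1), keepdims=True)
    return Tensor(
        out,
        parents=((x, lambda g: np.broadcast_to(g / (h * w), x.shape).copy()),),
    )


def broadcast_spatial(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Tile a (N, C, 1, 1) field to (N, C, out_h, out_w) (constant map)."""
    x = as_tensor(x)
    if x.shape[-2:] != (1, 1):
        raise ValueError("broadcast_spatial expects a 1x1 spatial field")
    out = np.broadcast_to(x.data, x.shape[:-2] + (out_h, out_w)).copy()
    return Tensor(
        out,
        parents=((x, lambda g: g.sum(axis=(-2, -1), keepdims=True)),),
    )


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _softmax(z, axis):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    x = as_tensor(x)
    s = _softmax(x.data, axis)

    def grad(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return s * (g - dot)

    return Tensor(s, parents=((x, grad),))


def softmax_cross_entropy(logits: Tensor, target_probs: np.ndarray, channel_axis: int = 1) -> Tensor:
    """Mean over pixels of -sum_k t_k log softmax(p)_k.

    ``target_probs`` is a fixed probability field with the logits' shape
    (one-hot or soft); it is not differentiated through.
    """
    logits = as_tensor(logits)
    t = np.asarray(target_probs, dtype=np.float64)
    if t.shape != logits.shape:
        raise ValueError(f"target shape {t.shape} != logits shape {logits.shape}")
    z = logits.data - logits.data.max(axis=channel_axis, keepdims=True)
    log_sm = z - np.log(np.exp(z).sum(axis=channel_axis, keepdims=True))
    n_pix = logits.data.size // logits.shape[channel_axis]
    loss = -(t * log_sm).sum() / n_pix
    sm = np.exp(log_sm)

    def grad(g):
        return g * (sm - t) / n_pix

    return Tensor(loss, parents=((logits, grad),))


def soft_iou_loss(logits: Tensor, target_probs: np.ndarray, channel_axis: int = 1, eps: float = 1e-8) -> Tensor:
    """1 - mean_k soft-Jaccard(softmax(p)_k, q_k)."""
    logits = as_tensor(logits)
    q = np.asarray(target_probs, dtype=np.float64)
    if q.shape != logits.shape:
        raise ValueError(f"target shape {q.shape} != logits shape {logits.shape}")
    s = _softmax(logits.data, channel_axis)
    axes = tuple(i for i in range(logits.ndim) if i != channel_axis)
    inter = (s * q).sum(axis=axes)
    union = s.sum(axis=axes) + q.sum(axis=axes) - inter
    iou = inter / (union + eps)
    k = logits.shape[channel_axis]
    loss = 1.0 - iou.mean()

    def grad(g):
        # d(iou_k)/ds_k = (q_k * U_k - I_k * (1 - q_k)) / U_k^2 per pixel
        sh = [1] * logits.ndim
        sh[channel_axis] = k
        u = (union + eps).reshape(sh)
        i_ = inter.reshape(sh)
        diou_ds = (q * u - i_ * (1 - q)) / (u * u)
        dloss_ds = -diou_ds / k
        dot = (dloss_ds * s).sum(axis=channel_axis, keepdims=True)
        return g * s * (dloss_ds - dot)

    return Tensor(loss, parents=((logits, grad),))
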