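"""Minimal reverse-mode automatic differentiation on numpy arrays.

Exactly the primitives a 3D encoder-decoder voxel network needs: 3D
convolution (im2col + GEMM), batch normalization, ReLU, 2x max pooling,
2x trilinear upsampling, channel concatenation, center cropping, softmax,
and the two losses used for training (masked MSE and class-weighted
cross-entropy).  Everything is float32; graphs are built define-by-run and
freed after ``backward``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "relu",
    "concat",
    "center_crop",
    "softmax_channels",
    "masked_mse",
    "weighted_cross_entropy",
    "conv3d",
    "crop_region",
    "max_pool3d",
    "upsample_trilinear",
    "upsample_region",
    "batch_norm",
]


class _GradMode:
    enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        self._prev = _GradMode.enabled
        _GradMode.enabled = False

    def __exit__(self, *exc):
        _GradMode.enabled = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GradMode.enabled


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        if self.data.size != 1:
            raise ValueError("item() needs a single-element tensor")
        return float(self.data.reshape(()))

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free graph state as we go; parameters keep their grads
                node._backward = None
                node._parents = ()

    # -- small arithmetic helpers (scalars only where training needs them) --
    def __mul__(self, s: float) -> "Tensor":
        out = _make(self.data * np.float32(s), (self,))
        if out.requires_grad:
            def bwd(g, self=self, s=s):
                _accum(self, g * np.float32(s))
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __add__(self, other: "Tensor") -> "Tensor":
        if not isinstance(other, Tensor):
            other = Tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            def bwd(g, a=self, b=other):
                _accum(a, g)
                _accum(b, g)
            out._backward = bwd
        return out


def _make(data, parents) -> Tensor:
    rg = _GradMode.enabled and any(p.requires_grad for p in parents)
    t = Tensor(data, requires_grad=rg)
    if rg:
        t._parents = tuple(p for p in parents if p.requires_grad)
    return t


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


# --------------------------------------------------------------------------
# elementwise / shape ops
# --------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = _make(np.where(mask, x.data, 0.0), (x,))
    if out.requires_grad:
        def bwd(g, x=x, mask=mask):
            _accum(x, g * mask)
        out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bwd(g, tensors=tensors, offsets=offsets, axis=axis):
            sl = [slice(None)] * g.ndim
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                sl[axis] = slice(a, b)
                _accum(t, g[tuple(sl)])
        out._backward = bwd
    return out


def center_crop(x: Tensor, edge: int) -> Tensor:
    """Center-crop the trailing 3 spatial axes to ``edge`` per axis.

    For a 40-voxel box cropped to 10 this selects indices 15..24.
    """
    spatial = x.data.shape[-3:]
    starts = [(s - edge) // 2 for s in spatial]
    if any(s < 0 for s in starts):
        raise ValueError(f"cannot crop spatial shape {spatial} to edge {edge}")
    sl = (Ellipsis,) + tuple(slice(s, s + edge) for s in starts)
    out = _make(x.data[sl], (x,))
    if out.requires_grad:
        def bwd(g, x=x, sl=sl):
            full = np.zeros_like(x.data)
            full[sl] = g
            _accum(x, full)
        out._backward = bwd
    return out


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 1 (channels)."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    out = _make(p, (x,))
    if out.requires_grad:
        def bwd(g, x=x, p=p):
            dot = (g * p).sum(axis=1, keepdims=True)
            _accum(x, p * (g - dot))
        out._backward = bwd
    return out


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------

def masked_mse(pred: Tensor, target: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean squared error over masked voxels only."""
    target = np.asarray(target, dtype=np.float32)
    mask = np.asarray(mask, dtype=bool)
    if pred.data.shape != target.shape or target.shape != mask.shape:
        raise ValueError("pred, target and mask must share a shape")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("mask selects no voxels")
    diff = np.where(mask, pred.data - target, 0.0)
    out = _make(np.float32((diff.astype(np.float64) ** 2).sum() / n), (pred,))
    if out.requires_grad:
        def bwd(g, pred=pred, diff=diff, n=n):
            _accum(pred, (2.0 / n) * diff * g)
        out._backward = bwd
    return out


def weighted_cross_entropy(probs: Tensor, truth: np.ndarray,
                           weights=(0.05, 0.95)) -> Tensor:
    """Class-weighted cross-entropy on two-channel probabilities.

    ``probs`` has shape (..., 2, D, H, W) with channel 0 = background and
    channel 1 = positive class; ``truth`` is binary with the channel axis
    removed.  Per-voxel terms ``-w_class * log p_true`` are averaged with the
    weights normalized (divided by the total weight of the batch).
    """
    p = probs.data
    if np.any(p < -1e-6) or np.any(p > 1 + 1e-6):
        raise ValueError("probabilities must lie in [0, 1]")
    truth = np.asarray(truth)
    ch_axis = p.ndim - 4
    if p.shape[ch_axis] != 2:
        raise ValueError("expected a two-channel probability field")
    t1 = (truth > 0.5)
    w0, w1 = float(weights[0]), float(weights[1])
    w = np.where(t1, w1, w0)
    eps = 1e-7
    p0 = np.take(p, 0, axis=ch_axis)
    p1 = np.take(p, 1, axis=ch_axis)
    p_true = np.where(t1, p1, p0)
    total_w = w.sum()
    loss = float((-w * np.log(np.clip(p_true, eps, 1.0))).sum() / total_w)
    out = _make(np.float32(loss), (probs,))
    if out.requires_grad:
        def bwd(g, probs=probs, p_true=p_true, t1=t1, w=w, total_w=total_w,
                ch_axis=ch_axis):
            gp_true = -w / np.clip(p_true, eps, 1.0) / total_w
            gfull = np.zeros_like(probs.data)
            idx1 = [slice(None)] * probs.data.ndim
            idx1[ch_axis] = 1
            idx0 = list(idx1)
            idx0[ch_axis] = 0
            gfull[tuple(idx1)] = np.where(t1, gp_true, 0.0)
            gfull[tuple(idx0)] = np.where(t1, 0.0, gp_true)
            _accum(probs, gfull * g)
        out._backward = bwd
    return out


# --------------------------------------------------------------------------
# spatial ops
# --------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B, C, D, H, W) -> (B*D*H*W, C*k^3) patch matrix (stride 1)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    # win: (B, C, D, H, W, k, k, k) -> (B, D, H, W, C, k, k, k)
    b, c = win.shape[0], win.shape[1]
    d, h, w = win.shape[2:5]
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7))
    return col.reshape(b * d * h * w, c * k ** 3)


#: Output-volume threshold above which the tap-sum path beats im2col
#: (it moves the same data but in long contiguous runs).
_TAPSUM_MIN_VOXELS = 8000


def _pad_cl(x: np.ndarray, pad: int) -> np.ndarray:
    """(B, C, D, H, W) -> zero-padded channel-last (B, D+2p, H+2p, W+2p, C)."""
    xcl = np.ascontiguousarray(x.transpose(0, 2, 3, 4, 1))
    if pad:
        xcl = np.pad(xcl, ((0, 0),) + ((pad, pad),) * 3 + ((0, 0),))
    return xcl


def _conv_forward(x: np.ndarray, wmat: np.ndarray, bias: np.ndarray | None,
                  k: int, pad: int) -> np.ndarray:
    b, c, d, h, w = x.shape
    cout = wmat.shape[1]
    od, oh, ow = (d + 2 * pad - k + 1, h + 2 * pad - k + 1, w + 2 * pad - k + 1)
    if od * oh * ow >= _TAPSUM_MIN_VOXELS and k > 1 and c >= 4:
        xp = _pad_cl(x, pad)
        wt = np.ascontiguousarray(wmat.reshape(c, k ** 3, cout).transpose(1, 0, 2))
        out = None
        tap = 0
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    v = xp[:, dz:dz + od, dy:dy + oh, dx:dx + ow, :]
                    contrib = v.reshape(-1, c) @ wt[tap]
                    out = contrib if out is None else out + contrib
                    tap += 1
    else:
        out = _im2col(x, k, pad) @ wmat
    if bias is not None:
        out += bias
    return np.ascontiguousarray(
        out.reshape(b, od, oh, ow, cout).transpose(0, 4, 1, 2, 3))


def _conv_weight_grad(x: np.ndarray, g: np.ndarray, k: int,
                      pad: int) -> np.ndarray:
    """Gradient w.r.t. the flat (cin*k^3, cout) weight matrix."""
    b, c = x.shape[:2]
    cout = g.shape[1]
    od, oh, ow = g.shape[2:]
    gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, cout)
    if od * oh * ow >= _TAPSUM_MIN_VOXELS and k > 1 and c >= 4:
        xp = _pad_cl(x, pad)
        gw = np.empty((k ** 3, c, cout), dtype=np.float32)
        tap = 0
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    v = xp[:, dz:dz + od, dy:dy + oh, dx:dx + ow, :]
                    gw[tap] = v.reshape(-1, c).T @ gmat
                    tap += 1
        return np.ascontiguousarray(
            gw.transpose(1, 0, 2)).reshape(c * k ** 3, cout)
    return _im2col(x, k, pad).T @ gmat


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None, k: int,
           pad: int | None = None) -> Tensor:
    """3D convolution, stride 1.

    ``pad=k//2`` (default) gives 'same' output; ``pad=0`` gives 'valid'
    output (each spatial edge shrinks by ``k - 1``).  ``weight`` is stored
    flat as ``(cin * k^3, cout)``; ``bias`` as ``(cout,)``.
    """
    if pad is None:
        pad = k // 2
    if x.data.ndim != 5:
        raise ValueError("conv3d expects (B, C, D, H, W) input")
    cin = x.data.shape[1]
    if weight.data.shape[0] != cin * k ** 3:
        raise ValueError("weight shape does not match input channels")
    y = _conv_forward(x.data, weight.data, None if bias is None else bias.data, k, pad)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = _make(y, parents)
    if out.requires_grad:
        def bwd(g, x=x, weight=weight, bias=bias, k=k, pad=pad):
            b, cout, d, h, w = g.shape
            if weight.requires_grad:
                _accum(weight, _conv_weight_grad(x.data, g, k, pad))
            if bias is not None and bias.requires_grad:
                _accum(bias, g.sum(axis=(0, 2, 3, 4)))
            if x.requires_grad:
                cin = x.data.shape[1]
                wk = weight.data.reshape(cin, k, k, k, cout)
                wflip = wk[:, ::-1, ::-1, ::-1, :]
                wT = np.ascontiguousarray(
                    wflip.transpose(4, 1, 2, 3, 0)).reshape(cout * k ** 3, cin)
                # gradient w.r.t. the input is the transposed convolution
                _accum(x, _conv_forward(g, wT, None, k, k - 1 - pad))
        out._backward = bwd
    return out


def crop_region(x: Tensor, start: int, stop: int) -> Tensor:
    """Crop [start, stop) on each of the trailing 3 spatial axes."""
    sl = (Ellipsis,) + (slice(start, stop),) * 3
    out = _make(x.data[sl], (x,))
    if out.requires_grad:
        def bwd(g, x=x, sl=sl):
            full = np.zeros_like(x.data)
            full[sl] = g
            _accum(x, full)
        out._backward = bwd
    return out


def max_pool3d(x: Tensor) -> Tensor:
    """2x2x2 max pooling, stride 2 (spatial dims must be even)."""
    b, c, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError("max_pool3d requires even spatial dimensions")
    xr = x.data.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2)
    xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(b, c, d // 2, h // 2, w // 2, 8)
    arg = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
    out = _make(y, (x,))
    if out.requires_grad:
        def bwd(g, x=x, arg=arg, shape=(b, c, d, h, w)):
            b, c, d, h, w = shape
            gr = np.zeros((b, c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
            np.put_along_axis(gr, arg[..., None], g[..., None], axis=-1)
            gr = gr.reshape(b, c, d // 2, h // 2, w // 2, 2, 2, 2)
            gr = gr.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(b, c, d, h, w)
            _accum(x, gr)
        out._backward = bwd
    return out


_UP_CACHE: dict[int, np.ndarray] = {}


def _upsample_matrix(n: int) -> np.ndarray:
    """(2n, n) linear-interpolation matrix (edge-clamped, cell-centered)."""
    if n not in _UP_CACHE:
        m = np.zeros((2 * n, n), dtype=np.float32)
        for o in range(2 * n):
            src = (o + 0.5) / 2.0 - 0.5
            i0 = int(np.floor(src))
            f = src - i0
            a = min(max(i0, 0), n - 1)
            b = min(max(i0 + 1, 0), n - 1)
            m[o, a] += 1.0 - f
            m[o, b] += f
        _UP_CACHE[n] = m
    return _UP_CACHE[n]


def _apply_axis(x: np.ndarray, m: np.ndarray, axis: int) -> np.ndarray:
    y = np.tensordot(x, m, axes=([axis], [1]))
    return np.ascontiguousarray(np.moveaxis(y, -1, axis))


def upsample_trilinear(x: Tensor) -> Tensor:
    """Double each of the trailing 3 spatial axes by trilinear interpolation."""
    d, h, w = x.data.shape[-3:]
    nd = x.data.ndim
    y = x.data
    for axis, n in zip((nd - 3, nd - 2, nd - 1), (d, h, w)):
        y = _apply_axis(y, _upsample_matrix(n), axis)
    out = _make(y, (x,))
    if out.requires_grad:
        def bwd(g, x=x, dims=(d, h, w), nd=nd):
            for axis, n in zip((nd - 3, nd - 2, nd - 1), dims):
                g = _apply_axis(g, _upsample_matrix(n).T, axis)
            _accum(x, g)
        out._backward = bwd
    return out


def upsample_region(x: Tensor, n_full: int, in_start: int,
                    out_start: int, out_len: int) -> Tensor:
    """Trilinear 2x upsampling restricted to a cubic output window.

    ``x`` holds a cubic crop of a ``n_full``-edge field starting at
    ``in_start`` (same on every spatial axis); the result is the output rows
    ``[out_start, out_start + out_len)`` of the full 2x upsampling.  The crop
    must cover every source voxel those rows interpolate from; values are
    identical to cropping the full upsampling.
    """
    in_len = x.data.shape[-1]
    full = _upsample_matrix(n_full)
    rows = full[out_start:out_start + out_len]
    if rows[:, :in_start].any() or rows[:, in_start + in_len:].any():
        raise ValueError("input crop does not cover the requested output window")
    m = np.ascontiguousarray(rows[:, in_start:in_start + in_len])
    nd = x.data.ndim
    y = x.data
    for axis in (nd - 3, nd - 2, nd - 1):
        y = _apply_axis(y, m, axis)
    out = _make(y, (x,))
    if out.requires_grad:
        def bwd(g, x=x, m=m, nd=nd):
            for axis in (nd - 3, nd - 2, nd - 1):
                g = _apply_axis(g, m.T, axis)
            _accum(x, g)
        out._backward = bwd
    return out


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running: dict,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over (B, D, H, W) per channel.

    ``running`` holds 'mean' and 'var' arrays updated in training mode and
    used directly in eval mode.
    """
    axes = (0, 2, 3, 4)
    c = x.data.shape[1]
    view = (1, c, 1, 1, 1)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mean
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mean = running["mean"]
        var = running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(view)) * inv.reshape(view)
    y = gamma.data.reshape(view) * xhat + beta.data.reshape(view)
    out = _make(y, (x, gamma, beta))
    if out.requires_grad:
        def bwd(g, x=x, gamma=gamma, beta=beta, xhat=xhat, inv=inv,
                training=training, view=view, axes=axes):
            if gamma.requires_grad:
                _accum(gamma, (g * xhat).sum(axis=axes))
            if beta.requires_grad:
                _accum(beta, g.sum(axis=axes))
            if x.requires_grad:
                gs = gamma.data.reshape(view)
                if training:
                    gxh = g * gs
                    t1 = gxh - gxh.mean(axis=axes, keepdims=True)
                    t2 = xhat * (gxh * xhat).mean(axis=axes, keepdims=True)
                    _accum(x, inv.reshape(view) * (t1 - t2))
                else:
                    _accum(x, g * gs * inv.reshape(view))
        out._backward = bwd
    return out
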