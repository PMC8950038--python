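"""Minimal reverse-mode automatic differentiation on numpy arrays.

Define-by-run tape holding exactly the operations the segmentation
networks need: 2-D convolution (stride 1, same padding, zero or wrap
mode), 2x2 max pooling, 2x2-stride-2 transposed convolution, nearest
2x upsampling, batch normalization, ReLU/sigmoid, channel concatenation,
broadcasting add/multiply and a fused weighted softmax cross-entropy.
Convolutions run as im2col matrix products.  Gradient correctness is
verified against finite differences in the test suite.

Array layout is channel-first: ``(N, C, H, W)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "conv2d", "conv_transpose2x2", "maxpool2x2", "upsample2_nearest",
    "relu", "sigmoid", "add", "mul", "concat", "batchnorm", "softmax",
    "weighted_softmax_cross_entropy",
]


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Reverse-mode sweep from this node (scalar by default)."""
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise and structural ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = backward
    return out


def relu(x) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = backward
    return out


def sigmoid(x) -> Tensor:
    x = _as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(s, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = backward
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# convolution / pooling / resampling
# ---------------------------------------------------------------------------

def _fold_padding(dxp: np.ndarray, p: int, H: int, W: int, mode: str) -> np.ndarray:
    """Collapse a padded-gradient array back to the unpadded input."""
    if p == 0:
        return dxp
    if mode == "zeros":
        return dxp[..., p:p + H, p:p + W]
    # wrap: padded row i < p maps to original row H - p + i, etc.
    dxp = dxp.copy()
    dxp[..., H:H + p, :] += dxp[..., 0:p, :]
    dxp[..., p:2 * p, :] += dxp[..., p + H:p + H + p, :]
    dxp = dxp[..., p:p + H, :]
    dxp[..., :, W:W + p] += dxp[..., :, 0:p]
    dxp[..., :, p:2 * p] += dxp[..., :, p + W:p + W + p]
    return dxp[..., :, p:p + W]


def conv2d(x, w, b=None, padding_mode: str = "zeros") -> Tensor:
    """Same-size 2-D convolution (cross-correlation), stride 1, odd kernel.

    ``x``: (N, C, H, W); ``w``: (F, C, k, k); ``b``: (F,) or None.
    ``padding_mode``: "zeros" (default) or "wrap" (periodic; makes the
    whole network exactly shift-equivariant).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    b = _as_tensor(b) if b is not None else None
    N, C, H, W = x.data.shape
    F, C2, kh, kw = w.data.shape
    assert C == C2 and kh == kw and kh % 2 == 1
    p = kh // 2
    np_mode = "constant" if padding_mode == "zeros" else "wrap"
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), mode=np_mode)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N, H * W, C * kh * kw)
    wmat = w.data.reshape(F, C * kh * kw)
    out_mat = cols @ wmat.T
    if b is not None:
        out_mat += b.data
    y = out_mat.transpose(0, 2, 1).reshape(N, F, H, W)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents=parents)

    def backward(g):
        gmat = g.reshape(N, F, H * W).transpose(0, 2, 1)  # (N, HW, F)
        if w.requires_grad:
            dw = np.einsum("nif,nik->fk", gmat, cols, optimize=True)
            w._accumulate(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(N, H, W, C, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + H, j:j + W] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            x._accumulate(_fold_padding(dxp, p, H, W, padding_mode))

    out._backward = backward
    return out


def maxpool2x2(x) -> Tensor:
    x = _as_tensor(x)
    N, C, H, W = x.data.shape
    assert H % 2 == 0 and W % 2 == 0
    blocks = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(N, C, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, parents=(x,))

    def backward(g):
        if x.requires_grad:
            dflat = np.zeros_like(flat)
            np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
            dx = dflat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(
                0, 1, 2, 4, 3, 5).reshape(N, C, H, W)
            x._accumulate(dx)

    out._backward = backward
    return out


def conv_transpose2x2(x, w, b=None) -> Tensor:
    """2x2-kernel, stride-2 transposed convolution (doubles H and W).

    ``x``: (N, C, H, W); ``w``: (C, F, 2, 2); output (N, F, 2H, 2W).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    b = _as_tensor(b) if b is not None else None
    N, C, H, W = x.data.shape
    C2, F, _, _ = w.data.shape
    assert C == C2
    y6 = np.einsum("nchw,cfij->nfhiwj", x.data, w.data, optimize=True)
    y = y6.reshape(N, F, 2 * H, 2 * W)
    if b is not None:
        y = y + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents=parents)

    def backward(g):
        g6 = g.reshape(N, F, H, 2, W, 2)
        if x.requires_grad:
            x._accumulate(np.einsum("nfhiwj,cfij->nchw", g6, w.data, optimize=True))
        if w.requires_grad:
            w._accumulate(np.einsum("nchw,nfhiwj->cfij", x.data, g6, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    out._backward = backward
    return out


def upsample2_nearest(x) -> Tensor:
    """Nearest-neighbour 2x upsampling (parameter-free)."""
    x = _as_tensor(x)
    N, C, H, W = x.data.shape
    y = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = Tensor(y, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

def batchnorm(x, gamma, beta, running_mean, running_var, training: bool,
              momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    In training mode batch statistics are used and the running buffers
    (plain ndarrays) are updated in place; in eval mode the running
    statistics are used.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1 - momentum)
        running_mean += momentum * mean
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mean = running_mean
        var = running_var
    std = np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) / std[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = Tensor(y, parents=(x, gamma, beta))

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = gamma.data[None, :, None, None] / std[None, :, None, None]
            if training:
                m = g.shape[0] * g.shape[2] * g.shape[3]
                gm = g.mean(axis=(0, 2, 3), keepdims=True)
                gxm = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
                x._accumulate(gs * (g - gm - xhat * gxm))
            else:
                x._accumulate(gs * g)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# softmax / loss
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Plain (non-graph) softmax for inference."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_softmax_cross_entropy(logits, target: np.ndarray,
                                   weights: np.ndarray) -> Tensor:
    """Fused per-pixel weighted cross-entropy over softmax(logits).

    ``logits``: (N, 3, H, W); ``target``: (N, H, W) int in {0,1,2};
    ``weights``: (3,).  Loss is normalized by the summed per-pixel
    weights so its scale is comparable across class balances.
    """
    logits = _as_tensor(logits)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    N, K, H, W = logits.data.shape
    onehot = np.eye(K, dtype=logits.data.dtype)[target].transpose(0, 3, 1, 2)
    wmap = np.asarray(weights, dtype=logits.data.dtype)[target]  # (N, H, W)
    wsum = wmap.sum()
    loss = -(wmap * (onehot * logp).sum(axis=1)).sum() / wsum
    out = Tensor(np.asarray(loss), parents=(logits,))

    def backward(g):
        if logits.requires_grad:
            p = np.exp(logp)
            grad = (p - onehot) * wmap[:, None, :, :] / wsum
            logits._accumulate(grad * g)

    out._backward = backward
    return out
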