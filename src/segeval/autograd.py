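"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just the operations a 2D encoder-decoder segmentation network needs:
3x3/1x1 convolution (im2col + BLAS matmul), ReLU, 2x2 max pooling,
average-pool downsampling, factor-2 bilinear upsampling, channel
concatenation, scalar gating, and a fused Dice + binary-cross-entropy
segmentation loss with an analytic gradient.

Tensors wrap float arrays of shape (N, C, H, W) (or scalars for gate
weights); ``backward()`` runs the tape in reverse topological order.
All operations are deterministic, so a fixed seed reproduces training
bit-for-bit on one machine.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray | float,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def _needs(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def add(a: Tensor, b: Tensor) -> Tensor:
    def bwd(g):
        a._accumulate(g)
        b._accumulate(g)

    return Tensor(a.data + b.data, parents=(a, b), backward=bwd if _needs(a, b) else None)


def scale(x: Tensor, s: Tensor) -> Tensor:
    """Multiply a feature map by a scalar gate."""

    def bwd(g):
        x._accumulate(g * s.data)
        s._accumulate(np.sum(g * x.data))

    return Tensor(x.data * s.data, parents=(x, s), backward=bwd if _needs(x, s) else None)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        x._accumulate(g * y * (1.0 - y))

    return Tensor(y, parents=(x,), backward=bwd if _needs(x) else None)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g):
        x._accumulate(g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=bwd if _needs(x) else None)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]

    def bwd(g):
        a._accumulate(g[:, :ca])
        b._accumulate(g[:, ca:])

    return Tensor(
        np.concatenate([a.data, b.data], axis=1),
        parents=(a, b),
        backward=bwd if _needs(a, b) else None,
    )


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------


def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    # xp: padded (N, C, Hp, Wp) -> (N, C*kh*kw, H*W) with H = Hp-kh+1
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    n, c, h, w, _, _ = view.shape
    return (
        view.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, h * w),
        (h, w),
    )


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, padding: int = 1) -> Tensor:
    """Same-size 2D convolution. weight: (K, C, kh, kw), bias: (K,)."""
    n, c, h, w = x.data.shape
    k, _, kh, kw = weight.data.shape
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    cols, (oh, ow) = _im2col(xp, kh, kw)
    wmat = weight.data.reshape(k, -1)
    out = np.matmul(wmat, cols)
    out = out.reshape(n, k, oh, ow) + bias.data[None, :, None, None]

    def bwd(g):
        gm = g.reshape(n, k, oh * ow)
        bias._accumulate(gm.sum(axis=(0, 2)))
        ckk = c * kh * kw
        dw = gm.transpose(1, 0, 2).reshape(k, -1) @ cols.transpose(1, 0, 2).reshape(
            ckk, -1
        ).T
        weight._accumulate(dw.reshape(weight.data.shape))
        if x.requires_grad or x._parents:
            dcols = np.matmul(wmat.T, gm)
            dcols = dcols.reshape(n, c, kh, kw, oh, ow)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + oh, j : j + ow] += dcols[:, :, i, j]
            if padding:
                x._accumulate(dxp[:, :, padding:-padding, padding:-padding])
            else:
                x._accumulate(dxp)

    return Tensor(out, parents=(x, weight, bias), backward=bwd)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def maxpool2x(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    blocks = (
        x.data.reshape(n, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h // 2, w // 2, 4)
    )
    idx = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        db = np.zeros_like(blocks)
        np.put_along_axis(db, idx[..., None], g[..., None], axis=-1)
        dx = (
            db.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        x._accumulate(dx)

    return Tensor(out, parents=(x,), backward=bwd if _needs(x) else None)


def avgpool(x: Tensor, factor: int) -> Tensor:
    n, c, h, w = x.data.shape
    f = factor
    out = x.data.reshape(n, c, h // f, f, w // f, f).mean(axis=(3, 5))

    def bwd(g):
        dx = np.repeat(np.repeat(g, f, axis=2), f, axis=3) / (f * f)
        x._accumulate(dx)

    return Tensor(out, parents=(x,), backward=bwd if _needs(x) else None)


_UP_MATRIX_CACHE: dict[tuple[int, str], np.ndarray] = {}


def _up_matrix(in_len: int, dtype) -> np.ndarray:
    """Dense (2L, L) interpolation matrix for factor-2 bilinear upsampling
    with half-pixel-center alignment and clamped edges. Applying it (and
    its transpose in backward) is a plain BLAS matmul, which beats
    scatter-add by a wide margin on CPU."""
    key = (in_len, np.dtype(dtype).str)
    if key not in _UP_MATRIX_CACHE:
        out_len = 2 * in_len
        src = (np.arange(out_len) + 0.5) / 2.0 - 0.5
        i0 = np.clip(np.floor(src).astype(int), 0, in_len - 1)
        i1 = np.clip(i0 + 1, 0, in_len - 1)
        frac = np.clip(src - np.floor(src), 0.0, 1.0)
        frac[src < 0] = 0.0
        u = np.zeros((out_len, in_len))
        rows = np.arange(out_len)
        np.add.at(u, (rows, i0), 1.0 - frac)
        np.add.at(u, (rows, i1), frac)
        _UP_MATRIX_CACHE[key] = u.astype(dtype)
    return _UP_MATRIX_CACHE[key]


def upsample2x_bilinear(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    dt = x.data.dtype
    uh = _up_matrix(h, dt)
    uw = _up_matrix(w, dt)
    out = np.matmul(np.matmul(uh, x.data), uw.T)

    def bwd(g):
        x._accumulate(np.matmul(np.matmul(uh.T, g), uw))

    return Tensor(out, parents=(x,), backward=bwd if _needs(x) else None)


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    """Upsample by a power-of-two factor via repeated 2x bilinear steps."""
    steps = int(round(np.log2(factor)))
    if 2**steps != factor:
        raise ValueError(f"upsample factor must be a power of 2, got {factor}")
    for _ in range(steps):
        x = upsample2x_bilinear(x)
    return x


# ---------------------------------------------------------------------------
# Segmentation loss
# ---------------------------------------------------------------------------


def dice_bce_loss(logits: Tensor, target: np.ndarray, eps: float = 1.0) -> Tensor:
    """Equal-weight sum of soft Dice loss and mean binary cross-entropy.

    Dice term per sample: 1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps),
    averaged over the batch; BCE computed from logits for stability.
    """
    z = logits.data
    t = np.asarray(target, dtype=z.dtype)
    from scipy.special import expit

    p = expit(z)
    # stable BCE: max(z,0) - z*t + log(1 + exp(-|z|))
    bce = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    bce_mean = bce.mean()

    axes = tuple(range(1, z.ndim))
    num = 2.0 * (p * t).sum(axis=axes) + eps
    den = p.sum(axis=axes) + t.sum(axis=axes) + eps
    dice_loss = (1.0 - num / den).mean()
    n = z.shape[0]

    def bwd(g):
        g = float(g)
        d_bce = (p - t) / bce.size
        # d/dp of -(num/den): (num - 2*t*den) / den^2, per sample
        d_dice_p = (
            num[(...,) + (None,) * (z.ndim - 1)]
            - 2.0 * t * den[(...,) + (None,) * (z.ndim - 1)]
        ) / (den**2)[(...,) + (None,) * (z.ndim - 1)]
        d_dice = d_dice_p * p * (1.0 - p) / n
        logits._accumulate(g * (d_bce + d_dice))

    return Tensor(
        np.asarray(bce_mean + dice_loss),
        parents=(logits,),
        backward=bwd if _needs(logits) else None,
    )


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam with the standard bias correction; state kept per parameter."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
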