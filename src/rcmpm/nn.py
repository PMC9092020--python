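"""Minimal reverse-mode automatic differentiation on numpy arrays.

Exactly the operations the contact-map refinement network needs: matrix
product, bias add, ReLU, channel concatenation, 1D/2D convolution (zero
padding, length/shape preserving), per-channel min-max normalization, row
tiling for the outer concatenation, and a fused softmax cross-entropy head.
Everything runs in float64, which keeps finite-difference gradient checks
meaningful.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """A numpy array plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor into every parameter."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    t.grad = g if t.grad is None else t.grad + g


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=float), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        _accumulate(a, g @ b.data.T)
        _accumulate(b, a.data.T @ g)

    return Tensor(out_data, parents=(a, b), backward=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"add shape mismatch: {a.data.shape} vs {b.data.shape}")

    def backward(g):
        _accumulate(a, g)
        _accumulate(b, g)

    return Tensor(a.data + b.data, parents=(a, b), backward=backward)


def add_bias(x: Tensor, b: Tensor) -> Tensor:
    """Add a per-channel bias (last axis) with broadcasting."""
    c = b.data.shape[0]

    def backward(g):
        _accumulate(x, g)
        _accumulate(b, g.reshape(-1, c).sum(axis=0))

    return Tensor(x.data + b.data, parents=(x, b), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        _accumulate(x, g * mask)

    return Tensor(np.where(mask, x.data, 0.0), parents=(x,), backward=backward)


def concat_last(tensors: list[Tensor]) -> Tensor:
    sizes = [t.data.shape[-1] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=-1)
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=-1)):
            _accumulate(t, piece)

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def tile_rows(x: Tensor, L: int, axis: int) -> Tensor:
    """Tile an (L, C) tensor into (L, L, C).

    axis=1: out[i, j] = x[i] (duplicate along the second axis);
    axis=0: out[i, j] = x[j] (the transpose on the first two axes).
    """
    if axis not in (0, 1):
        raise ValueError("axis must be 0 or 1")
    if axis == 1:
        out_data = np.broadcast_to(x.data[:, None, :], (x.shape[0], L, x.shape[1])).copy()
    else:
        out_data = np.broadcast_to(x.data[None, :, :], (L, x.shape[0], x.shape[1])).copy()

    def backward(g):
        _accumulate(x, g.sum(axis=axis))

    return Tensor(out_data, parents=(x,), backward=backward)


def minmax_normalize_array(x: np.ndarray) -> np.ndarray:
    """Per-channel (last axis) min-max map to [0, 1]; constant channels map to 0."""
    flat = x.reshape(-1, x.shape[-1])
    mn = flat.min(axis=0)
    rng = flat.max(axis=0) - mn
    safe = np.where(rng > 0, rng, 1.0)
    out = np.where(rng > 0, (flat - mn) / safe, 0.0)
    return out.reshape(x.shape)


def minmax(x: Tensor) -> Tensor:
    """Differentiable per-channel min-max normalization over all leading axes.

    The dependence of the channel minimum and maximum on the inputs is kept
    in the gradient (subgradients at the arg-min / arg-max elements).
    """
    shape = x.data.shape
    flat = x.data.reshape(-1, shape[-1])
    mn = flat.min(axis=0)
    mx = flat.max(axis=0)
    rng = mx - mn
    active = rng > 0
    safe = np.where(active, rng, 1.0)
    y = np.where(active, (flat - mn) / safe, 0.0)
    amin = flat.argmin(axis=0)
    amax = flat.argmax(axis=0)

    def backward(g):
        gf = g.reshape(-1, shape[-1])
        gx = gf / safe
        s = gf.sum(axis=0)
        t = (gf * y).sum(axis=0)
        cols = np.arange(shape[-1])
        corr_min = (t - s) / safe
        corr_max = -t / safe
        gx[amin, cols] += np.where(active, corr_min, 0.0)
        gx[amax, cols] += np.where(active, corr_max, 0.0)
        gx = np.where(active[None, :], gx, 0.0)
        _accumulate(x, gx.reshape(shape))

    return Tensor(y.reshape(shape), parents=(x,), backward=backward)


def _im2col_1d(xp: np.ndarray, k: int, L: int) -> np.ndarray:
    # xp: (L + k - 1, Cin) zero-padded input
    win = sliding_window_view(xp, k, axis=0)  # (L, Cin, k)
    return win.transpose(0, 2, 1).reshape(L, k * xp.shape[1])


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Length-preserving 1D convolution. x: (L, Cin), w: (k, Cin, Cout)."""
    k, cin, cout = w.data.shape
    L = x.data.shape[0]
    if x.data.shape[1] != cin:
        raise ValueError(f"conv1d channel mismatch: x has {x.data.shape[1]}, w {cin}")
    pad = (k - 1) // 2
    xp = np.pad(x.data, ((pad, k - 1 - pad), (0, 0)))
    cols = _im2col_1d(xp, k, L)
    w2 = w.data.reshape(k * cin, cout)
    out_data = cols @ w2
    if b is not None:
        out_data = out_data + b.data

    def backward(g):
        _accumulate(w, (cols.T @ g).reshape(k, cin, cout))
        if b is not None:
            _accumulate(b, g.sum(axis=0))
        if x.requires_grad:
            dcols = (g @ w2.T).reshape(L, k, cin)
            dxp = np.zeros_like(xp)
            for t in range(k):
                dxp[t : t + L] += dcols[:, t, :]
            _accumulate(x, dxp[pad : pad + L])

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Shape-preserving 2D convolution. x: (H, W, Cin), w: (k, k, Cin, Cout)."""
    k, k2, cin, cout = w.data.shape
    if k != k2:
        raise ValueError("conv2d kernel must be square")
    H, W_, xc = x.data.shape
    if xc != cin:
        raise ValueError(f"conv2d channel mismatch: x has {xc}, w {cin}")
    pad = (k - 1) // 2
    xp = np.pad(x.data, ((pad, k - 1 - pad), (pad, k - 1 - pad), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(0, 1))  # (H, W, Cin, k, k)
    cols = win.transpose(0, 1, 3, 4, 2).reshape(H * W_, k * k * cin)
    w2 = w.data.reshape(k * k * cin, cout)
    out_data = (cols @ w2).reshape(H, W_, cout)
    if b is not None:
        out_data = out_data + b.data

    def backward(g):
        g2 = g.reshape(H * W_, cout)
        _accumulate(w, (cols.T @ g2).reshape(k, k, cin, cout))
        if b is not None:
            _accumulate(b, g2.sum(axis=0))
        if x.requires_grad:
            dcols = (g2 @ w2.T).reshape(H, W_, k, k, cin)
            dxp = np.zeros_like(xp)
            for a in range(k):
                for c in range(k):
                    dxp[a : a + H, c : c + W_] += dcols[:, :, a, c, :]
            _accumulate(x, dxp[pad : pad + H, pad : pad + W_])

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=backward)


def softmax_array(logits: np.ndarray) -> np.ndarray:
    # non-finite logits propagate as NaN (callers detect divergence)
    with np.errstate(invalid="ignore", over="ignore"):
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy over all positions; targets are one-hot, last axis classes."""
    if logits.data.shape != targets.shape:
        raise ValueError(
            f"logits shape {logits.data.shape} != targets shape {targets.shape}"
        )
    n_positions = int(np.prod(targets.shape[:-1]))
    probs = softmax_array(logits.data)
    loss = -float(
        (targets * np.log(np.clip(probs, 1e-12, None))).sum()
    ) / n_positions

    def backward(g):
        _accumulate(logits, g * (probs - targets) / n_positions)

    return Tensor(loss, parents=(logits,), backward=backward)


class SGD:
    """Plain stochastic gradient descent, no momentum or weight decay."""

    def __init__(self, params: list[Tensor], lr: float):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.params = list(params)
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
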