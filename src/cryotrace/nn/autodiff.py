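"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

Provides exactly the operator set the voxel model needs: 3-D "same"
convolution (im2col with spatial chunking to bound memory), elementwise
arithmetic with broadcasting, ReLU/sigmoid, channel concatenation, global
average pooling, 1-D softmax (for learnable scale weights), dropout,
factor-2 average pooling and linear upsampling.  Gradients flow through a
tape built dynamically; ``Tensor.backward()`` runs a topological sweep.

float32 is used throughout; convolution accumulates in float32 which is
ample at the activations scales produced by He initialization.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# rough cap on the number of float32 elements materialized per im2col chunk
_COL_BUDGET = 1 << 24


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == tuple(shape):
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def scale(a: Tensor, s: float) -> Tensor:
    s = float(s)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s)

    return Tensor(a.data * s, parents=(a,), backward=backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return Tensor(a.data * mask, parents=(a,), backward=backward)


def sigmoid(a: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-a.data.astype(np.float64)))
    y = y.astype(np.float32)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * y * (1.0 - y))

    return Tensor(y, parents=(a,), backward=backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, o0, o1 in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(o0, o1)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def global_avg_pool(a: Tensor) -> Tensor:
    """Mean over the spatial axes of a (C, D, H, W) tensor, keeping dims."""
    n = a.data[0].size
    out_data = a.data.mean(axis=(1, 2, 3), keepdims=True)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.broadcast_to(g / n, a.shape).copy())

    return Tensor(out_data, parents=(a,), backward=backward)


def softmax_vector(a: Tensor) -> Tensor:
    """Softmax over a 1-D tensor (used for learnable scale weights)."""
    z = a.data - a.data.max()
    e = np.exp(z)
    y = (e / e.sum()).astype(np.float32)

    def backward(g):
        if a.requires_grad:
            a._accumulate(y * (g - float(np.dot(g, y))))

    return Tensor(y, parents=(a,), backward=backward)


def dropout(a: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return a
    keep = (rng.random(a.shape) >= p).astype(np.float32) / (1.0 - p)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * keep)

    return Tensor(a.data * keep, parents=(a,), backward=backward)


def _chunk_rows(D: int, H: int, W: int, ck: int) -> int:
    per_row = H * W * ck
    return max(1, min(D, _COL_BUDGET // max(1, per_row)))


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """'Same'-padded 3-D convolution.

    ``x``: (C_in, D, H, W); ``w``: (C_out, C_in, k, k, k) with odd ``k``;
    ``b``: (C_out,).  Implemented as chunked im2col + matmul; the backward
    pass recomputes the column matrix per chunk rather than caching it.
    """
    cin, D, H, W = x.shape
    cout, cin_w, k = w.shape[0], w.shape[1], w.shape[2]
    if cin_w != cin:
        raise ValueError(f"conv3d: input has {cin} channels, weight expects {cin_w}")
    if k % 2 != 1:
        raise ValueError("conv3d requires an odd kernel size")
    p = k // 2
    ck = cin * k * k * k
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p)))
    wmat = w.data.reshape(cout, ck)
    out = np.empty((cout, D, H, W), dtype=np.float32)
    chunk = _chunk_rows(D, H, W, ck)

    def cols_for(d0: int, d1: int) -> np.ndarray:
        sub = xp[:, d0 : d1 + 2 * p, :, :]
        win = sliding_window_view(sub, (k, k, k), axis=(1, 2, 3))
        # (C_in, dd, H, W, k,k,k) -> (dd*H*W, C_in*k^3)
        return np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(-1, ck)

    for d0 in range(0, D, chunk):
        d1 = min(D, d0 + chunk)
        cols = cols_for(d0, d1)
        out[:, d0:d1] = (cols @ wmat.T).T.reshape(cout, d1 - d0, H, W)
    out += b.data.reshape(-1, 1, 1, 1)

    def backward(g):
        if b.requires_grad:
            b._accumulate(g.sum(axis=(1, 2, 3)))
        gw = np.zeros_like(wmat) if w.requires_grad else None
        gxp = np.zeros_like(xp) if x.requires_grad else None
        for d0 in range(0, D, chunk):
            d1 = min(D, d0 + chunk)
            dd = d1 - d0
            gmat = g[:, d0:d1].reshape(cout, -1)  # (cout, P)
            if gw is not None:
                cols = cols_for(d0, d1)
                gw += gmat @ cols
            if gxp is not None:
                gcols = (gmat.T @ wmat).reshape(dd, H, W, cin, k, k, k)
                for a_ in range(k):
                    for b_ in range(k):
                        for c_ in range(k):
                            gxp[:, d0 + a_ : d0 + a_ + dd, b_ : b_ + H, c_ : c_ + W] += (
                                gcols[:, :, :, :, a_, b_, c_].transpose(3, 0, 1, 2)
                            )
        if gw is not None:
            w._accumulate(gw.reshape(w.shape))
        if gxp is not None:
            x._accumulate(gxp[:, p : p + D, p : p + H, p : p + W])

    return Tensor(out, parents=(x, w, b), backward=backward)


def avg_pool2(a: Tensor) -> Tensor:
    """Factor-2 average pooling over the spatial axes of (C, D, H, W)."""
    c, D, H, W = a.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError("avg_pool2 requires even spatial dimensions")
    r = a.data.reshape(c, D // 2, 2, H // 2, 2, W // 2, 2)
    out_data = r.mean(axis=(2, 4, 6))

    def backward(g):
        if a.requires_grad:
            ge = np.repeat(np.repeat(np.repeat(g, 2, 1), 2, 2), 2, 3) / 8.0
            a._accumulate(ge)

    return Tensor(out_data, parents=(a,), backward=backward)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Linear-interpolation matrix mapping n_in samples to n_out samples."""
    M = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    src = np.arange(n_out) * (n_in - 1) / (n_out - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    t = (src - lo).astype(np.float32)
    M[np.arange(n_out), lo] += 1.0 - t
    M[np.arange(n_out), hi] += t
    return M


def _apply_axis(arr: np.ndarray, M: np.ndarray, axis: int) -> np.ndarray:
    out = np.tensordot(M, arr, axes=(1, axis))
    return np.moveaxis(out, 0, axis)


def upsample_linear(a: Tensor, out_shape: tuple[int, int, int]) -> Tensor:
    """Trilinear upsampling of (C, D, H, W) to (C,) + out_shape."""
    mats = [
        _interp_matrix(out_shape[i], a.shape[1 + i]) for i in range(3)
    ]
    y = a.data
    for ax, M in enumerate(mats):
        y = _apply_axis(y, M, ax + 1)

    def backward(g):
        if a.requires_grad:
            gx = g
            for ax, M in enumerate(mats):
                gx = _apply_axis(gx, M.T, ax + 1)
            a._accumulate(gx.astype(np.float32))

    return Tensor(y.astype(np.float32), parents=(a,), backward=backward)
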