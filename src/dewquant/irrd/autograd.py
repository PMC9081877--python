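"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the edge network: 2-D convolution (im2col),
ReLU, elementwise add, channel concatenation and fixed bilinear
upsampling.  Tensors form a DAG through closures; ``backward`` seeds
gradients on output tensors and walks the graph in reverse topological
order.  Everything is single-threaded numpy, so results are bit-stable
for fixed inputs.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


class Tensor:
    """A numpy array node in the autodiff graph."""

    __slots__ = ("data", "grad", "_parents", "_backward", "name")

    def __init__(self, data, parents=(), backward=None, name=""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g


def backward(outputs: list[Tensor], grads: list[np.ndarray]) -> None:
    """Backpropagate seed gradients through the union graph of ``outputs``."""
    topo: list[Tensor] = []
    seen: set[int] = set()

    def visit(node: Tensor) -> None:
        stack = [(node, iter(node._parents))]
        if id(node) in seen:
            return
        seen.add(id(node))
        while stack:
            current, parents = stack[-1]
            advanced = False
            for parent in parents:
                if id(parent) not in seen:
                    seen.add(id(parent))
                    stack.append((parent, iter(parent._parents)))
                    advanced = True
                    break
            if not advanced:
                topo.append(current)
                stack.pop()

    for out, g in zip(outputs, grads):
        out.accumulate(g)
    for out in outputs:
        visit(out)
    for node in reversed(topo):
        if node.grad is not None and node._backward is not None:
            node._backward(node.grad)


def zero_grads(tensors) -> None:
    for t in tensors:
        t.grad = None


def _im2col(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(C, Hp, Wp) zero-padded input -> (C*k*k, Ho*Wo) column matrix."""
    c, hp, wp = xp.shape
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    windows = windows[:, ::stride, ::stride]  # (C, Ho, Wo, k, k)
    ho, wo = windows.shape[1], windows.shape[2]
    cols = windows.transpose(0, 3, 4, 1, 2).reshape(c * k * k, ho * wo)
    return np.ascontiguousarray(cols)


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """2-D convolution, zero padding k//2 ('same' for stride 1).

    x: (C, H, W); w: (O, C, k, k); b: (O,).  Output (O, H', W') with
    H' = (H + 2*(k//2) - k)//stride + 1.
    """
    o, c, k, _ = w.shape
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad)))
    cols = _im2col(xp, k, stride)
    hp, wp = xp.shape[1], xp.shape[2]
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    w_mat = w.data.reshape(o, c * k * k)
    y = (w_mat @ cols + b.data[:, None]).reshape(o, ho, wo)

    def _bwd(dy: np.ndarray) -> None:
        dy_mat = dy.reshape(o, ho * wo)
        w.accumulate((dy_mat @ cols.T).reshape(w.shape))
        b.accumulate(dy_mat.sum(axis=1))
        dcols = (w_mat.T @ dy_mat).reshape(c, k, k, ho, wo)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                    dcols[:, i, j]
                )
        if pad:
            dxp = dxp[:, pad:-pad, pad:-pad]
        x.accumulate(dxp)

    return Tensor(y, parents=(x, w, b), backward=_bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))
    out._backward = lambda dy: x.accumulate(dy * mask)
    return out


def add(x: Tensor, y: Tensor) -> Tensor:
    out = Tensor(x.data + y.data, parents=(x, y))

    def _bwd(dy: np.ndarray) -> None:
        x.accumulate(dy)
        y.accumulate(dy)

    out._backward = _bwd
    return out


def concat_channels(tensors: list[Tensor]) -> Tensor:
    sizes = [t.data.shape[0] for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=0), parents=tensors)

    def _bwd(dy: np.ndarray) -> None:
        start = 0
        for t, n in zip(tensors, sizes):
            t.accumulate(dy[start : start + n])
            start += n

    out._backward = _bwd
    return out


@lru_cache(maxsize=64)
def _bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) interpolation weights; half-pixel-centre convention."""
    a = np.zeros((n_out, n_in))
    scale = n_out / n_in
    src = (np.arange(n_out) + 0.5) / scale - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = src - i0
    a[np.arange(n_out), i0] += 1.0 - w1
    a[np.arange(n_out), i1] += w1
    return a


def upsample_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Resize (C, h, w) to (C, H, W) with separable bilinear interpolation."""
    h_in, w_in = x.data.shape[1], x.data.shape[2]
    h_out, w_out = out_hw
    ar = _bilinear_matrix(h_in, h_out)
    ac = _bilinear_matrix(w_in, w_out)
    y = np.matmul(np.matmul(ar, x.data), ac.T)
    out = Tensor(y, parents=(x,))
    out._backward = lambda dy: x.accumulate(np.matmul(np.matmul(ar.T, dy), ac))
    return out


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function (plain numpy, no graph)."""
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
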