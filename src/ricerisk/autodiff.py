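"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` accumulates gradients by reverse topological
traversal. The op set is exactly what the attention network in
:mod:`ricerisk.informer` needs: broadcast arithmetic, batched matmul,
reductions, indexing/scatter, softmax, ELU, 1-D convolution, max-pooling
and cumulative sums. Everything is double precision and fully deterministic.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int, list]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data: ArrayLike, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: Optional[np.ndarray] = None
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: Tuple["Tensor", ...] = ()

    # -- plumbing -----------------------------------------------------------

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # copy: the incoming array may be shared with another consumer
            self.grad = np.array(grad, dtype=np.float64)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += grad

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()
        stack: List[Tuple[Tensor, bool]] = [(self, False)]
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
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _make(data: np.ndarray, parents: Sequence[Tensor],
          backward: Callable[[np.ndarray], None]) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _as_tensor(x: Union[Tensor, ArrayLike]) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- arithmetic -------------------------------------------------------------


def add(a: Tensor, b: Union[Tensor, ArrayLike]) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g: np.ndarray) -> None:
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _make(data, (a, b), backward)


def mul(a: Tensor, b: Union[Tensor, ArrayLike]) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g: np.ndarray) -> None:
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    def backward(g: np.ndarray) -> None:
        a._accumulate(-g)

    return _make(-a.data, (a,), backward)


def sub(a: Tensor, b: Union[Tensor, ArrayLike]) -> Tensor:
    return add(a, neg(_as_tensor(b)))


def power(a: Tensor, exponent: float) -> Tensor:
    data = a.data**exponent

    def backward(g: np.ndarray) -> None:
        a._accumulate(g * exponent * a.data ** (exponent - 1))

    return _make(data, (a,), backward)


def div(a: Tensor, b: Union[Tensor, ArrayLike]) -> Tensor:
    return mul(_as_tensor(a), power(_as_tensor(b), -1.0))


def exp(a: Tensor) -> Tensor:
    data = np.exp(a.data)

    def backward(g: np.ndarray) -> None:
        a._accumulate(g * data)

    return _make(data, (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g: np.ndarray) -> None:
        a._accumulate(g / a.data)

    return _make(np.log(a.data), (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = np.matmul(a.data, b.data)

    def backward(g: np.ndarray) -> None:
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        a._accumulate(_unbroadcast(ga, a.shape))
        b._accumulate(_unbroadcast(gb, b.shape))

    return _make(data, (a, b), backward)


# -- reductions and shape ---------------------------------------------------


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g: np.ndarray) -> None:
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).copy())

    return _make(data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a: Tensor, shape: Tuple[int, ...]) -> Tensor:
    def backward(g: np.ndarray) -> None:
        a._accumulate(g.reshape(a.shape))

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes: Tuple[int, ...]) -> Tensor:
    inverse = np.argsort(axes)

    def backward(g: np.ndarray) -> None:
        a._accumulate(g.transpose(inverse))

    return _make(a.data.transpose(axes), (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray) -> None:
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _make(data, tuple(tensors), backward)


def getitem(a: Tensor, index) -> Tensor:
    data = a.data[index]

    def backward(g: np.ndarray) -> None:
        ga = np.zeros_like(a.data)
        np.add.at(ga, index, g)
        a._accumulate(ga)

    return _make(data, (a,), backward)


def row_scatter(base: Tensor, rows: Tensor, index: np.ndarray) -> Tensor:
    """Replace rows of ``base`` along axis -2 with ``rows``.

    ``base``: (..., L, d); ``rows``: (..., u, d); ``index``: integer array
    (..., u) of row positions. Positions not listed keep the base values.
    """
    idx = np.broadcast_to(index[..., None], rows.shape)
    data = base.data.copy()
    np.put_along_axis(data, idx, rows.data, axis=-2)

    def backward(g: np.ndarray) -> None:
        rows._accumulate(np.take_along_axis(g, idx, axis=-2))
        gb = g.copy()
        np.put_along_axis(gb, idx, 0.0, axis=-2)
        base._accumulate(gb)

    return _make(data, (base, rows), backward)


# -- nonlinearities ---------------------------------------------------------


def elu(a: Tensor) -> Tensor:
    """Exponential linear unit: x for x >= 0, e^x - 1 below."""
    data = np.where(a.data >= 0, a.data, np.expm1(a.data))

    def backward(g: np.ndarray) -> None:
        a._accumulate(g * np.where(a.data >= 0, 1.0, np.exp(a.data)))

    return _make(data, (a,), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g: np.ndarray) -> None:
        dot = (g * data).sum(axis=axis, keepdims=True)
        a._accumulate(data * (g - dot))

    return _make(data, (a,), backward)


def cumsum(a: Tensor, axis: int) -> Tensor:
    def backward(g: np.ndarray) -> None:
        a._accumulate(np.flip(np.cumsum(np.flip(g, axis), axis), axis))

    return _make(np.cumsum(a.data, axis), (a,), backward)


# -- structured ops for the network ----------------------------------------


def conv1d_same(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """1-D convolution along the time axis with same-padding.

    ``x``: (B, L, C_in); ``weight``: (K, C_in, C_out) with K odd;
    ``bias``: (C_out,). Output (B, L, C_out).
    """
    K = weight.shape[0]
    pad = (K - 1) // 2
    B, L, _ = x.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)  # (B,L,Cin,K)
    data = np.einsum("blik,kio->blo", windows, weight.data) + bias.data

    def backward(g: np.ndarray) -> None:
        gw = np.einsum("blik,blo->kio", windows, g)
        weight._accumulate(gw)
        bias._accumulate(g.sum(axis=(0, 1)))
        gxp = np.zeros_like(xp)
        for k in range(K):
            gxp[:, k : k + L, :] += np.matmul(g, weight.data[k].T)
        x._accumulate(gxp[:, pad : pad + L, :])

    return _make(data, (x, weight, bias), backward)


def maxpool1d(x: Tensor, kernel: int = 3, stride: int = 2, pad: int = 1) -> Tensor:
    """Max-pooling along the time axis of (B, L, C); output length ⌈L/2⌉
    for the default kernel-3 / stride-2 / pad-1 configuration."""
    B, L, C = x.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)), constant_values=-np.inf)
    windows = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=1)[:, ::stride]
    amax = windows.argmax(axis=-1)  # (B, Lout, C)
    data = np.take_along_axis(windows, amax[..., None], axis=-1)[..., 0]
    starts = np.arange(0, xp.shape[1] - kernel + 1, stride)

    def backward(g: np.ndarray) -> None:
        gxp = np.zeros_like(xp)
        pos = starts[None, :, None] + amax  # position in padded axis
        b_idx = np.arange(B)[:, None, None]
        c_idx = np.arange(C)[None, None, :]
        np.add.at(gxp, (b_idx, pos, c_idx), g)
        x._accumulate(gxp[:, pad : pad + L, :])

    return _make(data, (x,), backward)
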