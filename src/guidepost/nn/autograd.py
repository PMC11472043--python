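"""A compact reverse-mode automatic differentiation engine on numpy arrays.

Supports exactly the operations the off-target network and its likelihood
losses need: broadcasting arithmetic, matmul, 1-D convolution and max
pooling, sigmoid/tanh/relu/exp/log/log-gamma, reductions, slicing and
concatenation.  Everything is float64; gradients are accumulated by a
topological sweep over the recorded tape.  Correctness is pinned down by
finite-difference tests in the test suite.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import special


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum grad over the axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Optional[Callable[[np.ndarray], None]] = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)
        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.data.shape))

        return Tensor(self.data / other.data, parents=(self, other), backward=bw)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __matmul__(self, other):
        other = Tensor._lift(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bw)

    def pow_const(self, exponent: float) -> "Tensor":
        def bw(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))
        return Tensor(self.data ** exponent, parents=(self,), backward=bw)

    # -- elementwise nonlinearities --------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data)
        return Tensor(out_data, parents=(self,), backward=bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)
        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def sigmoid(self):
        out_data = special.expit(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))
        return Tensor(out_data, parents=(self,), backward=bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data ** 2))
        return Tensor(out_data, parents=(self,), backward=bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)
        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def softplus(self):
        # log(1 + e^x), stable form
        out_data = np.logaddexp(0.0, self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * special.expit(self.data))
        return Tensor(out_data, parents=(self,), backward=bw)

    def lgamma(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g * special.digamma(self.data))
        return Tensor(special.gammaln(self.data), parents=(self,), backward=bw)

    def clamp(self, lo: float, hi: float) -> "Tensor":
        """Clip values; the gradient is zero outside [lo, hi]."""
        inside = (self.data >= lo) & (self.data <= hi)

        def bw(g):
            if self.requires_grad:
                self._accum(g * inside)
        return Tensor(np.clip(self.data, lo, hi), parents=(self,), backward=bw)

    def maximum(self, other) -> "Tensor":
        """Elementwise max; ties send the full gradient to ``self``."""
        other = Tensor._lift(other)
        take_self = self.data >= other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * take_self, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~take_self, other.data.shape))

        return Tensor(np.maximum(self.data, other.data), parents=(self, other), backward=bw)

    # -- reductions / shape ops ------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())
        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        orig = self.data.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))
        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bw)

    def transpose(self, axes: Tuple[int, ...]):
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))
        return Tensor(self.data.transpose(axes), parents=(self,), backward=bw)

    def __getitem__(self, idx):
        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        return Tensor(self.data[idx], parents=(self,), backward=bw)

    # -- backprop ---------------------------------------------------------

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bw)


def stack_last_axis_slices(x: Tensor, starts, size: int, axis: int) -> List[Tensor]:
    """Convenience: a list of contiguous slices of ``x`` along ``axis``."""
    slicer = [slice(None)] * x.data.ndim
    out = []
    for s in starts:
        sl = list(slicer)
        sl[axis] = slice(s, s + size)
        out.append(x[tuple(sl)])
    return out


def conv1d(x: Tensor, weight: Tensor, bias: Tensor, padding: int = 0) -> Tensor:
    """1-D convolution (cross-correlation): x (B,C,L), weight (O,C,K) -> (B,O,L').

    L' = L + 2*padding - K + 1.  Implemented with a sliding-window view and
    einsum; the backward pass mirrors the same contraction.
    """
    B, C, L = x.data.shape
    O, C2, K = weight.data.shape
    assert C == C2, "channel mismatch"
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # (B,C,L',K)
    out_data = np.einsum("bclk,ock->bol", win, weight.data, optimize=True) + \
        bias.data[None, :, None]

    def bw(g):
        if weight.requires_grad:
            weight._accum(np.einsum("bclk,bol->ock", win, g, optimize=True))
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gx = np.zeros_like(xp)
            # scatter each kernel tap back onto the padded input
            Lp = out_data.shape[2]
            for k in range(K):
                gx[:, :, k:k + Lp] += np.einsum("bol,ock->bcl", g,
                                                weight.data[:, :, k:k + 1],
                                                optimize=True)
            if padding:
                gx = gx[:, :, padding:-padding]
            x._accum(gx)

    return Tensor(out_data, parents=(x, weight, bias), backward=bw)


def max_pool1d(x: Tensor, kernel: int = 2, stride: int = 2) -> Tensor:
    """Max pooling over the last axis of (B,C,L); trailing remainder dropped."""
    B, C, L = x.data.shape
    Lp = (L - kernel) // stride + 1
    idx = np.arange(Lp) * stride
    win = np.stack([x.data[:, :, i:i + kernel] for i in idx], axis=2)  # (B,C,Lp,k)
    arg = win.argmax(axis=3)
    out_data = win.max(axis=3)

    def bw(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            b_idx, c_idx, l_idx = np.meshgrid(
                np.arange(B), np.arange(C), np.arange(Lp), indexing="ij")
            np.add.at(gx, (b_idx, c_idx, idx[l_idx] + arg), g)
            x._accum(gx)

    return Tensor(out_data, parents=(x,), backward=bw)
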