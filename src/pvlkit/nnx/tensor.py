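"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical substrate for the volumetric network: a `Tensor`
wraps an ndarray, records the operation that produced it, and `backward()`
accumulates gradients through the recorded graph in reverse topological
order. Only the operations required by the model family are implemented
(elementwise arithmetic, matmul, reductions, reshape/transpose, 3-D
convolution, and the usual activations). Everything is float32 by default
to keep the memory footprint of volumetric batches manageable.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # Sum over leading axes added by broadcasting.
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # Sum over axes that were broadcast from size 1.
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")
    __array_priority__ = 100  # so ndarray + Tensor defers to Tensor

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" name={self.name!r}" if self.name else ""
        return f"Tensor(shape={self.shape}, grad={self.requires_grad}{tag})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        g = g.astype(np.float32, copy=False)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode accumulation from this (typically scalar) node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     requires_grad=self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.shape))

            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, requires_grad=self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     requires_grad=self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.shape))

            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data,
                     requires_grad=self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(
                        _unbroadcast(-g * self.data / other.data ** 2, other.shape))

            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, requires_grad=self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(
                g * exponent * self.data ** (exponent - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     requires_grad=self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def bw(g):
                if self.requires_grad:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    self._accumulate(_unbroadcast(ga, self.shape))
                if other.requires_grad:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accumulate(_unbroadcast(gb, other.shape))

            out._backward = bw
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def bw(g):
                if axis is not None and not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    g = np.expand_dims(g, axes)
                self._accumulate(np.broadcast_to(g, self.shape))

            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        """Detached max (no gradient) — used only for numerical stabilization."""
        return Tensor(self.data.max(axis=axis, keepdims=keepdims))

    # ------------------------------------------------------------- shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), requires_grad=self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), requires_grad=self.requires_grad)
        if out.requires_grad:
            inv = np.argsort(axes)
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    # ------------------------------------------------------------ elementwise
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, requires_grad=self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, requires_grad=self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g * 0.5 / val)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, requires_grad=self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, requires_grad=self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g * val * (1.0 - val))
        return out

    def clip(self, lo: float, hi: float):
        """Clip values; gradient passes only where values were inside range."""
        mask = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), requires_grad=self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along `axis`."""
        shifted = self - self.max(axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: tuple[int, int, int], padding: tuple[int, int, int]) -> Tensor:
    """3-D cross-correlation, NCDHW layout.

    Implemented as a sum over kernel offsets of strided-slice einsums, which
    keeps peak memory at one activation map instead of a full im2col matrix.
    """
    sd, sh, sw = stride
    pd, ph, pw = padding
    kD, kH, kW = weight.shape[2:]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    N, C, D, H, W = xp.shape
    Do = (D - kD) // sd + 1
    Ho = (H - kH) // sh + 1
    Wo = (W - kW) // sw + 1
    Cout = weight.shape[0]
    # im2col as a strided view: (N, C, Do, Ho, Wo, kD, kH, kW), zero copy
    win = np.lib.stride_tricks.sliding_window_view(
        xp, (kD, kH, kW), axis=(2, 3, 4))[:, :, ::sd, ::sh, ::sw]
    cols = np.ascontiguousarray(win).reshape(N, C, Do * Ho * Wo, kD * kH * kW)
    wmat = weight.data.reshape(Cout, C * kD * kH * kW)
    # (N, L, C*k^3) @ (C*k^3, Cout) -> (N, L, Cout)
    cols2 = cols.transpose(0, 2, 1, 3).reshape(N, Do * Ho * Wo, -1)
    out = (cols2 @ wmat.T).transpose(0, 2, 1).reshape(N, Cout, Do, Ho, Wo)
    out = np.ascontiguousarray(out)
    if bias is not None:
        out += bias.data.reshape(1, -1, 1, 1, 1)

    requires = x.requires_grad or weight.requires_grad or (
        bias is not None and bias.requires_grad)
    res = Tensor(out, requires_grad=requires)
    if requires:
        parents = [x, weight] + ([bias] if bias is not None else [])
        res._parents = tuple(parents)

        def bw(g):
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3, 4)))
            # g as (N, L, Cout)
            gmat = g.reshape(N, Cout, -1).transpose(0, 2, 1)
            if weight.requires_grad:
                # (Cout, L*N) @ (L*N, C*k^3)
                gw = np.tensordot(gmat, cols2, axes=([0, 1], [0, 1]))
                weight._accumulate(gw.reshape(weight.shape))
            if x.requires_grad:
                gcols = (gmat @ wmat).reshape(N, Do, Ho, Wo, C, kD, kH, kW)
                gxp = np.zeros_like(xp)
                for i in range(kD):
                    for j in range(kH):
                        for k in range(kW):
                            gxp[:, :, i:i + sd * Do:sd, j:j + sh * Ho:sh,
                                k:k + sw * Wo:sw] += gcols[
                                    :, :, :, :, :, i, j, k].transpose(
                                        0, 4, 1, 2, 3)
                if pd or ph or pw:
                    gxp = gxp[:, :, pd:D - pd, ph:H - ph, pw:W - pw]
                x._accumulate(gxp)

        res._backward = bw
    return res
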