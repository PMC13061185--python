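"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements the small set of differentiable primitives the network needs:
broadcast arithmetic, matmul, reductions, shape ops, elementwise
nonlinearities, 2-D convolution (dense and depthwise) and integer gather.
Gradients are accumulated on every node of the tape, which is what lets
Grad-CAM read the gradient at an interior feature map after a single
backward pass from a logit.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "gather", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str | None = None):
        arr = np.asarray(data)
        if arr.dtype != np.float32 and arr.dtype != np.float64:
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or bool(parents)
        self._parents = parents
        self._backward = backward
        self.name = name

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-topological sweep; seeds with ones for scalar outputs."""
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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        if isinstance(x, Tensor):
            return x
        if isinstance(x, (int, float)):
            return Tensor(np.float32(x))
        return Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(_unbroadcast(g, self.shape)),
                                   other._accum(_unbroadcast(g, other.shape)))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(_unbroadcast(g * other.data, self.shape)),
                                   other._accum(_unbroadcast(g * self.data, other.shape)))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def _bw(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.shape))
        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def _bw(g):
            a, b = self.data, other.data
            if a.ndim == 2 and b.ndim == 2:
                self._accum(g @ b.T)
                other._accum(a.T @ g)
            else:  # batched matmul
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
                self._accum(_unbroadcast(ga, self.shape))
                other._accum(_unbroadcast(gb, other.shape))
        out._backward = _bw
        return out

    # -- elementwise ----------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / np.maximum(out.data, 1e-30))
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data ** 2))
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), parents=(self,))
        out._backward = lambda g: self._accum(g * out.data * (1.0 - out.data))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def gelu(self):
        """Gaussian error linear unit (tanh approximation), fused primitive."""
        c = np.float32(np.sqrt(2.0 / np.pi))
        x = self.data
        u = c * (x + np.float32(0.044715) * x * x * x)
        th = np.tanh(u)
        out = Tensor(np.float32(0.5) * x * (1.0 + th), parents=(self,))

        def _bw(g):
            du = c * (1.0 + np.float32(3 * 0.044715) * x * x)
            self._accum(g * (0.5 * (1.0 + th) + 0.5 * x * (1.0 - th * th) * du))
        out._backward = _bw
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        shape = self.shape

        def _bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape).copy())
                return
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            if not keepdims:
                g = np.expand_dims(g, tuple(a % len(shape) for a in axes))
            self._accum(np.broadcast_to(g, shape).copy())
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in ((axis,) if isinstance(axis, int) else axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out


# ----------------------------------------------------------------------
def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])
    out._backward = _bw
    return out


def gather(table: Tensor, index: np.ndarray) -> Tensor:
    """Index a parameter table with a constant integer array (scatter-add backward)."""
    index = np.asarray(index)
    out = Tensor(table.data[index], parents=(table,))

    def _bw(g):
        acc = np.zeros_like(table.data)
        np.add.at(acc, index, g)
        table._accum(acc)
    out._backward = _bw
    return out


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C, OH, OW, kh, kw) window view (copied)."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return np.ascontiguousarray(win[:, :, ::stride, ::stride])


def _col2im(dcols: np.ndarray, xp_shape, kh: int, kw: int, stride: int) -> np.ndarray:
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    oh, ow = dcols.shape[2], dcols.shape[3]
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += dcols[:, :, :, :, i, j]
    return dxp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, depthwise: bool = False) -> Tensor:
    """2-D convolution (cross-correlation) on NCHW input.

    Dense: w is (C_out, C_in, kh, kw).  Depthwise: w is (C, 1, kh, kw) and each
    channel is filtered independently.
    """
    n, c, h, wd = x.shape
    kh, kw = w.shape[-2:]
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data
    cols = _im2col(xp, kh, kw, stride)  # (N,C,OH,OW,kh,kw)
    if depthwise:
        out_data = np.einsum("nchwij,cij->nchw", cols, w.data[:, 0], optimize=True)
    else:
        out_data = np.einsum("nchwij,ocij->nohw", cols, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, parents=parents)

    def _bw(g):
        if depthwise:
            dw = np.einsum("nchwij,nchw->cij", cols, g, optimize=True)[:, None]
            dcols = np.einsum("nchw,cij->nchwij", g, w.data[:, 0], optimize=True)
        else:
            dw = np.einsum("nchwij,nohw->ocij", cols, g, optimize=True)
            dcols = np.einsum("nohw,ocij->nchwij", g, w.data, optimize=True)
        dxp = _col2im(dcols, xp.shape, kh, kw, stride)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accum(dxp)
        w._accum(dw)
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
    out._backward = _bw
    return out
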