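"""Reverse-mode automatic differentiation on NumPy arrays.

A minimal tape-based engine providing exactly the operations the
segmentation network needs: broadcasted arithmetic, matmul, reductions,
shape manipulation, the pointwise nonlinearities, and 2D (dilated /
strided) convolution plus 2x2-stride-2 transposed convolution as fused
primitives.  Gradients flow through a dynamically built DAG; ``backward``
runs a topological sweep.

Arrays keep whatever float dtype they are created with, so the same graph
code runs in float32 for training and float64 when a test wants tight
agreement with an independent oracle.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "conv_transpose2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # ---- graph construction helpers -------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # ---- basic info ------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- arithmetic ------------------------------------------------------

    def __add__(self, other):
        a, b = self, self._wrap(other)
        out_data = a.data + b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return self._make(out_data, (a, b), backward)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, self._wrap(other)
        out_data = a.data * b.data

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return self._make(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        b = self._wrap(other)
        return self * b ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * exponent * a.data ** (exponent - 1.0))

        return self._make(out_data, (a,), backward)

    # ---- pointwise nonlinearities ---------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data)

        return self._make(out_data, (a,), backward)

    def log(self):
        a = self
        out_data = np.log(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return self._make(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0
        out_data = a.data * mask

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * mask)

        return self._make(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (a,), backward)

    # ---- reductions ------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape))
            else:
                axes = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, axes)
                a._accumulate(np.broadcast_to(g, a.data.shape))

        return self._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- shape manipulation ---------------------------------------------

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = a.data.reshape(shape)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.reshape(a.data.shape))

        return self._make(out_data, (a,), backward)

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out_data = a.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.transpose(inv))

        return self._make(out_data, (a,), backward)

    def __getitem__(self, idx):
        a = self
        out_data = a.data[idx]

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                full[idx] = g
                a._accumulate(full)

        return self._make(out_data, (a,), backward)

    # ---- linear algebra --------------------------------------------------

    def matmul(self, other):
        a, b = self, self._wrap(other)
        out_data = a.data @ b.data

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return self._make(out_data, (a, b), backward)

    __matmul__ = matmul

    # ---- autodiff driver -------------------------------------------------

    def backward(self, grad=None):
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis`, differentiable in every input."""
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tensors, backward)


def _im2col_indices(h_out, w_out, k, stride, dilation):
    i = (np.arange(h_out) * stride)[:, None, None, None] + (np.arange(k) * dilation)[None, None, :, None]
    j = (np.arange(w_out) * stride)[None, :, None, None] + (np.arange(k) * dilation)[None, None, None, :]
    return i, j


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, dilation: int = 1, padding: int = 0) -> Tensor:
    """2D convolution (cross-correlation) on NCHW input.

    `weight` has shape (C_out, C_in, k, k).  Uses an im2col + GEMM forward
    and a 9-slice col2im backward, so both directions run through BLAS.
    """
    x = Tensor._wrap(x)
    b_, c_in, h, w = x.data.shape
    c_out, c_in_w, k, k2 = weight.data.shape
    if k != k2:
        raise ValueError("only square kernels supported")
    if c_in != c_in_w:
        raise ValueError(f"input has {c_in} channels, weight expects {c_in_w}")
    eff = (k - 1) * dilation + 1
    h_out = (h + 2 * padding - eff) // stride + 1
    w_out = (w + 2 * padding - eff) // stride + 1
    if h_out < 1 or w_out < 1:
        raise ValueError("kernel larger than padded input")

    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    ii, jj = _im2col_indices(h_out, w_out, k, stride, dilation)
    # patches: (B, C, Hout, Wout, k, k) -> (B*Hout*Wout, C*k*k)
    patches = xp[:, :, ii, jj]                      # (B, C, Hout, Wout, k, k)
    patches = patches.transpose(0, 2, 3, 1, 4, 5).reshape(b_ * h_out * w_out, c_in * k * k)
    w_mat = weight.data.reshape(c_out, c_in * k * k)
    out_mat = patches @ w_mat.T                     # (B*Hout*Wout, C_out)
    out_data = out_mat.reshape(b_, h_out, w_out, c_out).transpose(0, 3, 1, 2)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g_mat = g.transpose(0, 2, 3, 1).reshape(b_ * h_out * w_out, c_out)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            weight._accumulate((g_mat.T @ patches).reshape(weight.data.shape))
        if x.requires_grad:
            dpatch = (g_mat @ w_mat).reshape(b_, h_out, w_out, c_in, k, k)
            dpatch = dpatch.transpose(0, 3, 4, 5, 1, 2)   # (B, C, k, k, Hout, Wout)
            dxp = np.zeros_like(xp)
            for u in range(k):
                for v in range(k):
                    dxp[:, :,
                        u * dilation: u * dilation + h_out * stride: stride,
                        v * dilation: v * dilation + w_out * stride: stride] += dpatch[:, :, u, v]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    return Tensor._make(out_data, parents, backward)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Transposed convolution with kernel 2, stride 2 (exact 2x upsampling).

    `weight` has shape (C_in, C_out, 2, 2).  With stride equal to the
    kernel size the output windows do not overlap, so the operation is a
    single einsum and reshape.
    """
    x = Tensor._wrap(x)
    b_, c_in, h, w = x.data.shape
    c_in_w, c_out, k, _ = weight.data.shape
    if c_in != c_in_w:
        raise ValueError(f"input has {c_in} channels, weight expects {c_in_w}")
    out = np.einsum("bchw,couv->bohuwv", x.data, weight.data, optimize=True)
    out_data = out.reshape(b_, c_out, h * k, w * k)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g6 = g.reshape(b_, c_out, h, k, w, k)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            weight._accumulate(np.einsum("bchw,bohuwv->couv", x.data, g6, optimize=True))
        if x.requires_grad:
            x._accumulate(np.einsum("bohuwv,couv->bchw", g6, weight.data, optimize=True))

    return Tensor._make(out_data, parents, backward)
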