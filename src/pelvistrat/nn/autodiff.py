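"""A small reverse-mode automatic-differentiation engine on NumPy arrays.

The classifier in this package is a modified 3D residual network; the engine
implements exactly the operator set that network needs — 3D convolution via
im2col/GEMM, batch normalization, linear maps, ReLU/sigmoid, broadcasting
arithmetic, axis reductions (sum/mean/max), concatenation, and a numerically
stable binary cross-entropy on logits.  Every intermediate tensor keeps its
gradient after ``backward()``, which is what lets GradCAM++ read the gradient
map of an internal layer without any extra machinery.

All computation is float32.  Gradient correctness is covered by
finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "reshape",
    "sum_axes",
    "mean_axes",
    "max_axes",
    "concat",
    "conv3d",
    "batch_norm",
    "bce_with_logits",
]


class Tensor:
    """A NumPy array with a backward closure linking it to its parents."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this tensor through the recorded graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.accumulate(np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # Convenience arithmetic (constants are treated as non-differentiable).
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape})"


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        a.accumulate(_unbroadcast(g, a.data.shape))
        b.accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = backward
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))

    def backward(g):
        a.accumulate(g @ b.data.T)
        b.accumulate(a.data.T @ g)

    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))
    out._backward = lambda g: x.accumulate(g * mask)
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(s, parents=(x,))
    out._backward = lambda g: x.accumulate(g * s * (1.0 - s))
    return out


def reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape
    out = Tensor(x.data.reshape(shape), parents=(x,))
    out._backward = lambda g: x.accumulate(g.reshape(old))
    return out


def sum_axes(x: Tensor, axes, keepdims: bool = False) -> Tensor:
    axes = tuple(axes) if np.iterable(axes) else (axes,)
    out = Tensor(x.data.sum(axis=axes, keepdims=keepdims), parents=(x,))

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        x.accumulate(np.broadcast_to(g, x.data.shape).astype(np.float32))

    out._backward = backward
    return out


def mean_axes(x: Tensor, axes, keepdims: bool = False) -> Tensor:
    axes = tuple(axes) if np.iterable(axes) else (axes,)
    count = float(np.prod([x.data.shape[a] for a in axes]))
    out = Tensor(x.data.mean(axis=axes, keepdims=keepdims), parents=(x,))

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        x.accumulate(np.broadcast_to(g / count, x.data.shape).astype(np.float32))

    out._backward = backward
    return out


def max_axes(x: Tensor, axes, keepdims: bool = False) -> Tensor:
    """Max over ``axes``; the gradient flows to the first arg-max element."""
    axes = tuple(sorted(a % x.data.ndim for a in (axes if np.iterable(axes) else (axes,))))
    moved = np.moveaxis(x.data, axes, range(x.data.ndim - len(axes), x.data.ndim))
    lead_shape = moved.shape[: x.data.ndim - len(axes)]
    flat = moved.reshape(lead_shape + (-1,))
    idx = np.argmax(flat, axis=-1)
    vals = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out_shape = list(x.data.shape)
    for a in axes:
        out_shape[a] = 1
    data = vals.reshape(out_shape) if keepdims else vals
    out = Tensor(data, parents=(x,))

    def backward(g):
        gflat = np.zeros_like(flat)
        gv = g.reshape(lead_shape) if not keepdims else g.reshape(lead_shape)
        np.put_along_axis(gflat, idx[..., None], gv[..., None], axis=-1)
        gmoved = gflat.reshape(moved.shape)
        x.accumulate(np.moveaxis(gmoved, range(x.data.ndim - len(axes), x.data.ndim), axes))

    out._backward = backward
    return out


def concat(tensors, axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]

    def backward(g):
        start = 0
        for t, size in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + size)
            t.accumulate(g[tuple(sl)])
            start += size

    out._backward = backward
    return out


def _conv_output_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """3D cross-correlation of (N,C,D,H,W) with (Cout,Cin,k,k,k), im2col + GEMM."""
    N, C, D, H, W = x.data.shape
    Cout, Cin, k, _, _ = w.data.shape
    assert Cin == C, "channel mismatch"
    p, s = padding, stride
    Do, Ho, Wo = (_conv_output_size(n, k, s, p) for n in (D, H, W))

    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p > 0 else x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::s, ::s, ::s][:, :, :Do, :Ho, :Wo]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(N * Do * Ho * Wo, C * k**3)
    wmat = w.data.reshape(Cout, -1)
    out_data = cols @ wmat.T
    if b is not None:
        out_data += b.data
    out_data = out_data.reshape(N, Do, Ho, Wo, Cout).transpose(0, 4, 1, 2, 3)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(np.ascontiguousarray(out_data), parents=parents)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 4, 1).reshape(N * Do * Ho * Wo, Cout)
        w.accumulate((gmat.T @ cols).reshape(w.data.shape))
        if b is not None:
            b.accumulate(gmat.sum(axis=0))
        dcols = gmat @ wmat  # (N*Do*Ho*Wo, C*k^3)
        dwin = dcols.reshape(N, Do, Ho, Wo, C, k, k, k).transpose(0, 4, 1, 2, 3, 5, 6, 7)
        dxp = np.zeros((N, C, D + 2 * p, H + 2 * p, W + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dxp[:, :, i : i + Do * s : s, j : j + Ho * s : s, l : l + Wo * s : s] += dwin[..., i, j, l]
        x.accumulate(dxp[:, :, p : p + D, p : p + H, p : p + W] if p > 0 else dxp)

    out._backward = backward
    return out


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over (N, D, H, W) per channel; updates running stats in place."""
    axes = (0, 2, 3, 4)
    shape = (1, x.data.shape[1], 1, 1, 1)
    if training:
        mu = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
        running_mean *= 1 - momentum
        running_mean += momentum * mu.reshape(-1)
        running_var *= 1 - momentum
        running_var += momentum * var.reshape(-1)
    else:
        mu = running_mean.reshape(shape).astype(np.float32)
        var = running_var.reshape(shape).astype(np.float32)
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * ivar
    out = Tensor(gamma.data.reshape(shape) * xhat + beta.data.reshape(shape), parents=(x, gamma, beta))
    m = float(np.prod([x.data.shape[a] for a in axes]))

    def backward(g):
        gamma.accumulate((g * xhat).sum(axis=axes))
        beta.accumulate(g.sum(axis=axes))
        dxhat = g * gamma.data.reshape(shape)
        if training:
            dx = (
                ivar / m * (m * dxhat - dxhat.sum(axis=axes, keepdims=True) - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True))
            )
        else:
            dx = dxhat * ivar
        x.accumulate(dx.astype(np.float32))

    out._backward = backward
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits.

    Mathematically identical to -[y log s + (1-y) log(1-s)] with s the sigmoid
    score, but evaluated as softplus(z) - y*z to avoid log-of-0.
    """
    y = np.asarray(targets, dtype=np.float32).reshape(logits.data.shape)
    z = logits.data
    loss = np.logaddexp(0.0, z) - y * z
    out = Tensor(loss.mean(), parents=(logits,))
    n = float(z.size)

    def backward(g):
        s = 1.0 / (1.0 + np.exp(-z))
        logits.accumulate((g * (s - y) / n).astype(np.float32))

    out._backward = backward
    return out
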