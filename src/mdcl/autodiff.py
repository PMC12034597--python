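"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operation set needed by the segmentation networks
and losses in this package: broadcasting arithmetic, matmul, elementwise
nonlinearities, shape manipulation (reshape / transpose / concat / pad /
roll), index gather (the backbone of im2col convolution and nearest
upsampling) and axis reductions.  Gradients are accumulated by a reverse
topological sweep from a scalar root.

Dtype policy: tensors keep the dtype of the array they were built from
(float32 for network training, float64 for loss-arithmetic checks).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather",
    "pad",
    "roll",
    "relu",
    "gelu",
    "log",
    "exp",
    "sqrt",
    "clip_min",
    "softmax",
    "as_tensor",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were broadcast from size 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

    # ----- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ----- autograd core --------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from this scalar tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar root")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS post-order (graphs can be deep)
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
            if node._parents:
                node.grad = None  # free interior gradients eagerly

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # ----- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))
        out.requires_grad = self.requires_grad or other.requires_grad

        def _bw(g):
            self._accumulate(g)
            other._accumulate(g)

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out.requires_grad = self.requires_grad
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))
        out.requires_grad = self.requires_grad or other.requires_grad

        def _bw(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))
        out.requires_grad = self.requires_grad or other.requires_grad

        def _bw(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / (other.data**2))

        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _parents=(self,))
        out.requires_grad = self.requires_grad
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))
        out.requires_grad = self.requires_grad or other.requires_grad
        a, b = self.data, other.data

        def _bw(g):
            if b.ndim == 1:
                ga = np.outer(g, b) if a.ndim == 2 else g[..., None] * b
                gb = a.T @ g if a.ndim == 2 else (a * g[..., None]).sum(
                    axis=tuple(range(a.ndim - 1))
                )
            elif b.ndim == 2 and a.ndim > 2:
                # batched activations x shared 2D weight: collapse the
                # batch into one 2D product (much cheaper than batched
                # matmul followed by a sum over the batch axes)
                ga = g @ b.T
                gb = a.reshape(-1, a.shape[-1]).T @ g.reshape(-1, g.shape[-1])
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            self._accumulate(ga)
            other._accumulate(gb)

        out._backward = _bw
        return out

    # ----- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out.requires_grad = self.requires_grad
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out.requires_grad = self.requires_grad
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    # ----- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))
        out.requires_grad = self.requires_grad

        def _bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
                return
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            if not keepdims:
                g = np.expand_dims(g, tuple(a % self.data.ndim for a in axes))
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ----- functional ops ---------------------------------------------------------


def relu(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out = Tensor(np.maximum(t.data, 0), _parents=(t,))
    out.requires_grad = t.requires_grad
    out._backward = lambda g: t._accumulate(g * (t.data > 0))
    return out


_GELU_C = np.sqrt(2.0 / np.pi)


def gelu(t: Tensor) -> Tensor:
    """tanh-approximated GELU."""
    t = as_tensor(t)
    x = t.data
    inner = _GELU_C * (x + 0.044715 * x**3)
    th = np.tanh(inner)
    out = Tensor(0.5 * x * (1.0 + th), _parents=(t,))
    out.requires_grad = t.requires_grad

    def _bw(g):
        sech2 = 1.0 - th**2
        d = 0.5 * (1.0 + th) + 0.5 * x * sech2 * _GELU_C * (1.0 + 3 * 0.044715 * x**2)
        t._accumulate(g * d)

    out._backward = _bw
    return out


def log(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out = Tensor(np.log(t.data), _parents=(t,))
    out.requires_grad = t.requires_grad
    out._backward = lambda g: t._accumulate(g / t.data)
    return out


def exp(t: Tensor) -> Tensor:
    t = as_tensor(t)
    out = Tensor(np.exp(t.data), _parents=(t,))
    out.requires_grad = t.requires_grad
    e = out.data  # avoid closing over `out` (reference cycle)
    out._backward = lambda g: t._accumulate(g * e)
    return out


def sqrt(t: Tensor) -> Tensor:
    return as_tensor(t) ** 0.5


def clip_min(t: Tensor, floor: float) -> Tensor:
    """max(t, floor); gradient passes only where t > floor."""
    t = as_tensor(t)
    out = Tensor(np.maximum(t.data, floor), _parents=(t,))
    out.requires_grad = t.requires_grad
    out._backward = lambda g: t._accumulate(g * (t.data > floor))
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    out.requires_grad = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = _bw
    return out


def pad(t: Tensor, widths) -> Tensor:
    """Zero padding; `widths` as for np.pad."""
    t = as_tensor(t)
    out = Tensor(np.pad(t.data, widths), _parents=(t,))
    out.requires_grad = t.requires_grad
    slices = tuple(slice(b, b + n) for (b, _), n in zip(widths, t.data.shape))

    def _bw(g):
        t._accumulate(g[slices])

    out._backward = _bw
    return out


def roll(t: Tensor, shift, axes) -> Tensor:
    t = as_tensor(t)
    out = Tensor(np.roll(t.data, shift, axis=axes), _parents=(t,))
    out.requires_grad = t.requires_grad
    neg = tuple(-s for s in shift) if isinstance(shift, (tuple, list)) else -shift
    out._backward = lambda g: t._accumulate(np.roll(g, neg, axis=axes))
    return out


def gather(t: Tensor, idx: np.ndarray) -> Tensor:
    """Index the second axis of a 2D tensor: out[n, *s] = t[n, idx[*s]].

    The workhorse of im2col convolution and nearest-neighbour upsampling;
    backward scatter-adds into the source positions.
    """
    t = as_tensor(t)
    if t.ndim != 2:
        raise ValueError("gather expects a 2D tensor (batch, features)")
    out = Tensor(np.take(t.data, idx, axis=1), _parents=(t,))
    out.requires_grad = t.requires_grad
    flat_idx = idx.ravel()

    def _bw(g):
        n, f = t.data.shape
        g2 = g.reshape(n, -1)
        # bincount-based scatter-add (much faster than np.add.at)
        acc = np.empty((n, f), dtype=g2.dtype)
        for i in range(n):
            acc[i] = np.bincount(flat_idx, weights=g2[i], minlength=f)
        t._accumulate(acc)

    out._backward = _bw
    return out


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis`."""
    t = as_tensor(t)
    m = t.data.max(axis=axis, keepdims=True)  # constant shift, gradient-free
    e = exp(t - m)
    return e / e.sum(axis=axis, keepdims=True)
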