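"""Layers and an SGD optimizer built on :mod:`mdcl.autodiff`.

Convolutions (2D and 3D) are expressed as im2col gathers followed by a
matrix multiply, so their gradients come for free from the engine's
`gather` and `matmul` primitives.  Index tables are cached per input
shape, which keeps repeated forward passes cheap at the small scales
this package trains at.
"""

from __future__ import annotations

import itertools

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Module", "Parameter", "Linear", "LayerNorm", "ConvNd", "InstanceNorm", "upsample_nearest", "SGD"]


def Parameter(data: np.ndarray) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class: parameter discovery by attribute walk, train/eval flag."""

    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        if set(params) != set(state):
            missing = set(params) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=p.data.dtype).copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (n_in + n_out))
        self.weight = Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        # nonzero bias init: keeps token embeddings of constant inputs
        # away from the degenerate zero-variance point of LayerNorm
        b = 1.0 / np.sqrt(n_in)
        self.bias = Parameter(rng.uniform(-b, b, size=n_out))

    def __call__(self, x: Tensor) -> Tensor:
        shape = x.shape
        flat = x.reshape(-1, shape[-1]) if x.ndim != 2 else x
        out = flat @ self.weight + self.bias
        if x.ndim != 2:
            out = out.reshape(*shape[:-1], self.weight.shape[1])
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / ad.sqrt(var + self.eps) * self.gamma + self.beta


class InstanceNorm(Module):
    """Per-sample, per-channel normalization over spatial axes (affine)."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        # x: (N, C, *spatial)
        sp_axes = tuple(range(2, x.ndim))
        mu = x.mean(axis=sp_axes, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=sp_axes, keepdims=True)
        bshape = (1, -1) + (1,) * (x.ndim - 2)
        g = self.gamma.reshape(bshape)
        b = self.beta.reshape(bshape)
        return xc / ad.sqrt(var + self.eps) * g + b


class ConvNd(Module):
    """N-dimensional convolution (N = 2 or 3) via cached im2col gather.

    Input (batch, in_ch, *spatial) -> output (batch, out_ch, *out_spatial)
    with 'same'-style zero padding of kernel//2 and the given stride.
    """

    def __init__(self, ndim: int, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int | None = None):
        super().__init__()
        self.ndim = ndim
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.kernel = kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel**ndim
        fan_out = out_ch * kernel**ndim
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        self.weight = Parameter(rng.uniform(-bound, bound, size=(fan_in, out_ch)))
        b = 1.0 / np.sqrt(fan_in)
        self.bias = Parameter(rng.uniform(-b, b, size=out_ch))
        self._idx_cache: dict[tuple[int, ...], tuple[np.ndarray, tuple[int, ...], tuple[int, ...]]] = {}

    def _indices(self, spatial: tuple[int, ...]):
        key = spatial
        cached = self._idx_cache.get(key)
        if cached is not None:
            return cached
        k, s, p = self.kernel, self.stride, self.padding
        padded = tuple(n + 2 * p for n in spatial)
        out_sp = tuple((n + 2 * p - k) // s + 1 for n in spatial)
        # flat index over (C, *padded)
        strides = np.cumprod((1,) + padded[::-1])[::-1]  # strides for (C,*padded)
        sp_strides = strides[1:]
        ch_stride = strides[0]
        offs = []
        for delta in itertools.product(range(k), repeat=self.ndim):
            offs.append(sum(d * st for d, st in zip(delta, sp_strides)))
        offs = np.asarray(offs)  # (k^ndim,)
        origins = []
        for o in itertools.product(*[range(0, n) for n in out_sp]):
            origins.append(sum(oi * s * st for oi, st in zip(o, sp_strides)))
        origins = np.asarray(origins)  # (n_out,)
        ch = np.arange(self.in_ch) * ch_stride  # (C,)
        # idx[n_out, C*k^ndim]
        idx = (origins[:, None, None] + ch[None, :, None] + offs[None, None, :])
        idx = idx.reshape(len(origins), self.in_ch * len(offs))
        result = (idx, padded, out_sp)
        self._idx_cache[key] = result
        return result

    def __call__(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        spatial = x.shape[2:]
        idx, padded, out_sp = self._indices(tuple(spatial))
        p = self.padding
        if p:
            widths = [(0, 0), (0, 0)] + [(p, p)] * self.ndim
            x = ad.pad(x, widths)
        flat = x.reshape(n, -1)
        cols = ad.gather(flat, idx)              # (N, n_out, C*k^d)
        out = cols @ self.weight + self.bias     # (N, n_out, out_ch)
        out = out.transpose(0, 2, 1)
        return out.reshape(n, self.out_ch, *out_sp)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling of all spatial axes of (N, C, *spatial)."""
    n, c = x.shape[:2]
    spatial = x.shape[2:]
    out_sp = tuple(s * factor for s in spatial)
    grids = np.meshgrid(*[np.arange(s) // factor for s in out_sp], indexing="ij")
    flat_sp = np.zeros(out_sp, dtype=np.int64)
    stride = 1
    for g, s in zip(reversed(grids), reversed(spatial)):
        flat_sp = flat_sp + g * stride
        stride *= s
    ch = np.arange(c).reshape((c,) + (1,) * len(out_sp)) * int(np.prod(spatial))
    idx = ch + flat_sp[None]
    out = ad.gather(x.reshape(n, -1), idx)
    return out  # already (N, C, *out_sp) because idx has that shape minus batch


class SGD:
    """Plain SGD with momentum (default 0.9), optional weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= (self.lr * v).astype(p.data.dtype, copy=False)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
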