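"""The two segmentation networks.

* ``SwinUNet2D`` — a U-shaped 2D network whose encoder/decoder blocks use
  hierarchical windowed multi-head self-attention with shifted windows
  (patch embedding -> attention stages with patch merging -> symmetric
  expansion with skip connections -> pixel-level head).
* ``UNet3D`` — a 3D convolutional encoder-decoder with skip connections.

Both output per-element class probabilities via a softmax head and are
pure functions of (weights, input) in evaluation mode.  Tiny presets
(32x32 slices, 32x32x8 patches) make single-sample overfitting feasible
on one CPU; the default presets mirror a clinical deployment scale.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

__all__ = [
    "Net2DConfig",
    "Net3DConfig",
    "SwinUNet2D",
    "UNet3D",
    "build_net2d",
    "build_net3d",
    "forward_2d",
    "forward_3d",
    "save_checkpoint",
    "load_checkpoint",
    "checkpoint_id",
    "TINY_2D",
    "TINY_3D",
]


# --------------------------------------------------------------------------
# configs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Net2DConfig:
    """Configuration of the 2D windowed-attention U-shaped network."""

    in_channels: int = 1
    n_classes: int = 2
    embed_dim: int = 24
    depths: tuple[int, ...] = (2, 2)
    n_heads: tuple[int, ...] = (3, 6)
    window: int = 4
    patch_size: int = 4
    input_size: tuple[int, int] = (32, 32)
    mlp_ratio: float = 2.0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        down = self.patch_size * 2 ** (len(self.depths) - 1)
        for s in self.input_size:
            if s % down != 0:
                raise ValueError(
                    f"input size {self.input_size} not divisible by total "
                    f"downsampling factor {down}"
                )


@dataclass(frozen=True)
class Net3DConfig:
    """Configuration of the 3D convolutional encoder-decoder."""

    in_channels: int = 1
    n_classes: int = 2
    base_channels: int = 8
    n_levels: int = 3
    input_size: tuple[int, int, int] = (32, 32, 8)

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        down = 2 ** (self.n_levels - 1)
        for s in self.input_size:
            if s % down != 0:
                raise ValueError(
                    f"input size {self.input_size} not divisible by 2^(n_levels-1)={down}"
                )


TINY_2D = Net2DConfig()
TINY_3D = Net3DConfig()


# --------------------------------------------------------------------------
# 2D network with windowed self-attention
# --------------------------------------------------------------------------


class _WindowAttention(nn.Module):
    """Multi-head self-attention inside non-overlapping (optionally
    cyclically shifted) square windows of a (B, H, W, C) token grid."""

    def __init__(self, dim: int, heads: int, window: int, shift: int, rng):
        super().__init__()
        if dim % heads:
            raise ValueError("dim must divide evenly into heads")
        self.dim = dim
        self.heads = heads
        self.window = window
        self.shift = shift
        self.scale = (dim // heads) ** -0.5
        self.q = nn.Linear(dim, dim, rng)
        self.k = nn.Linear(dim, dim, rng)
        self.v = nn.Linear(dim, dim, rng)
        self.proj = nn.Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        win = min(self.window, h, w)
        shift = self.shift if win < min(h, w) else 0
        if shift:
            x = ad.roll(x, (-shift, -shift), axes=(1, 2))
        nh, nw = h // win, w // win
        t = win * win
        # partition into windows: (B*nh*nw, win*win, C)
        x = x.reshape(b, nh, win, nw, win, c).transpose(0, 1, 3, 2, 4, 5)
        x = x.reshape(b * nh * nw, t, c)

        def split_heads(lin):
            y = lin(x).reshape(-1, t, self.heads, c // self.heads)
            return y.transpose(0, 2, 1, 3)  # (B', heads, T, hd)

        q, k, v = split_heads(self.q), split_heads(self.k), split_heads(self.v)
        attn = ad.softmax((q @ k.transpose(0, 1, 3, 2)) * self.scale, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(-1, t, c)
        out = self.proj(out)
        out = out.reshape(b, nh, nw, win, win, c).transpose(0, 1, 3, 2, 4, 5)
        out = out.reshape(b, h, w, c)
        if shift:
            out = ad.roll(out, (shift, shift), axes=(1, 2))
        return out


class _SwinBlock(nn.Module):
    def __init__(self, dim: int, heads: int, window: int, shift: int, mlp_ratio: float, rng):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.attn = _WindowAttention(dim, heads, window, shift, rng)
        self.norm2 = nn.LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(ad.gelu(self.fc1(self.norm2(x))))


class _PatchMerging(nn.Module):
    def __init__(self, dim: int, rng):
        super().__init__()
        self.norm = nn.LayerNorm(4 * dim)
        self.reduce = nn.Linear(4 * dim, 2 * dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        x = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        x = x.reshape(b, h // 2, w // 2, 4 * c)
        return self.reduce(self.norm(x))


class _PatchExpand(nn.Module):
    """Double the token grid, halving channels."""

    def __init__(self, dim: int, rng):
        super().__init__()
        self.expand = nn.Linear(dim, 2 * dim, rng)
        self.norm = nn.LayerNorm(dim // 2)

    def __call__(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        x = self.expand(x)  # (b, h, w, 2c)
        x = x.reshape(b, h, w, 2, 2, c // 2).transpose(0, 1, 3, 2, 4, 5)
        x = x.reshape(b, 2 * h, 2 * w, c // 2)
        return self.norm(x)


class _FinalExpand(nn.Module):
    """Expand token grid by `factor` back to pixel resolution."""

    def __init__(self, dim: int, factor: int, rng):
        super().__init__()
        self.factor = factor
        self.expand = nn.Linear(dim, factor * factor * dim, rng)
        self.norm = nn.LayerNorm(dim)

    def __call__(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        f = self.factor
        x = self.expand(x).reshape(b, h, w, f, f, c).transpose(0, 1, 3, 2, 4, 5)
        x = x.reshape(b, h * f, w * f, c)
        return self.norm(x)


class SwinUNet2D(nn.Module):
    """U-shaped 2D network with shifted-window self-attention blocks."""

    def __init__(self, cfg: Net2DConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        d, w = cfg.embed_dim, cfg.window

        def blocks(dim, heads, depth):
            return [
                _SwinBlock(dim, heads, w, (w // 2) if i % 2 else 0, cfg.mlp_ratio, rng)
                for i in range(depth)
            ]

        self.embed = nn.ConvNd(2, cfg.in_channels, d, kernel=cfg.patch_size,
                               rng=rng, stride=cfg.patch_size, padding=0)
        self.embed_norm = nn.LayerNorm(d)
        self.enc = blocks(d, cfg.n_heads[0], cfg.depths[0])
        self.merge = _PatchMerging(d, rng)
        self.bottleneck = blocks(2 * d, cfg.n_heads[1], cfg.depths[1])
        self.expand = _PatchExpand(2 * d, rng)
        self.skip_fuse = nn.Linear(2 * d, d, rng)
        self.dec = blocks(d, cfg.n_heads[0], cfg.depths[0])
        self.final = _FinalExpand(d, cfg.patch_size, rng)
        self.head = nn.Linear(d, cfg.n_classes, rng)

    def __call__(self, x: Tensor) -> Tensor:
        """(N, in_ch, H, W) logits -> (N, n_classes, H, W)."""
        x = self.embed(x)                      # (N, d, h, w)
        x = x.transpose(0, 2, 3, 1)            # token grid (N, h, w, d)
        x = self.embed_norm(x)
        for blk in self.enc:
            x = blk(x)
        skip = x
        x = self.merge(x)
        for blk in self.bottleneck:
            x = blk(x)
        x = self.expand(x)
        x = ad.concat([x, skip], axis=-1)
        x = self.skip_fuse(x)
        for blk in self.dec:
            x = blk(x)
        x = self.final(x)
        x = self.head(x)                       # (N, H, W, n_classes)
        return x.transpose(0, 3, 1, 2)


# --------------------------------------------------------------------------
# 3D convolutional encoder-decoder
# --------------------------------------------------------------------------


class _ConvBlock3D(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, rng):
        super().__init__()
        self.conv = nn.ConvNd(3, in_ch, out_ch, kernel=3, rng=rng)
        self.norm = nn.InstanceNorm(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.relu(self.norm(self.conv(x)))


class UNet3D(nn.Module):
    """3D encoder-decoder with strided-conv downsampling, nearest-neighbour
    upsampling and skip connections; softmax applied by :func:`forward_3d`."""

    def __init__(self, cfg: Net3DConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        chans = [cfg.base_channels * 2**i for i in range(cfg.n_levels)]
        self.enc = []
        prev = cfg.in_channels
        for c in chans[:-1]:
            self.enc.append(_ConvBlock3D(prev, c, rng))
            prev = c
        self.down = [
            nn.ConvNd(3, chans[i], chans[i + 1], kernel=3, rng=rng, stride=2)
            for i in range(cfg.n_levels - 1)
        ]
        self.bottleneck = [
            _ConvBlock3D(chans[-1], chans[-1], rng),
            _ConvBlock3D(chans[-1], chans[-1], rng),
        ]
        self.up_conv = [
            nn.ConvNd(3, chans[i + 1], chans[i], kernel=3, rng=rng)
            for i in reversed(range(cfg.n_levels - 1))
        ]
        self.dec = [
            _ConvBlock3D(2 * chans[i], chans[i], rng)
            for i in reversed(range(cfg.n_levels - 1))
        ]
        self.head = nn.ConvNd(3, chans[0], cfg.n_classes, kernel=1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        """(N, in_ch, X, Y, Z) logits -> (N, n_classes, X, Y, Z)."""
        skips = []
        for enc, down in zip(self.enc, self.down):
            x = enc(x)
            skips.append(x)
            x = down(x)
        for blk in self.bottleneck:
            x = blk(x)
        for up, dec, skip in zip(self.up_conv, self.dec, reversed(skips)):
            x = nn.upsample_nearest(x, 2)
            x = up(x)
            x = ad.concat([x, skip], axis=1)
            x = dec(x)
        return self.head(x)


# --------------------------------------------------------------------------
# forward contracts
# --------------------------------------------------------------------------


def build_net2d(cfg: Net2DConfig = TINY_2D, seed: int = 0) -> SwinUNet2D:
    return SwinUNet2D(cfg, seed)


def build_net3d(cfg: Net3DConfig = TINY_3D, seed: int = 0) -> UNet3D:
    return UNet3D(cfg, seed)


def _prep(x, expected_spatial, ndim_spatial):
    """Normalize input to a float32 (N, 1, *spatial) tensor; remember batching."""
    arr = x.data if isinstance(x, Tensor) else np.asarray(x)
    batched = arr.ndim != ndim_spatial
    if not batched:
        arr = arr[None]
    if arr.ndim == ndim_spatial + 1:  # (N, *spatial) -> add channel
        arr = arr[:, None]
    if tuple(arr.shape[2:]) != tuple(expected_spatial):
        raise ValueError(
            f"input spatial shape {arr.shape[2:]} does not match model "
            f"config input_size {tuple(expected_spatial)}"
        )
    if isinstance(x, Tensor):
        return x, batched
    return Tensor(arr.astype(np.float32, copy=False)), batched


def forward_2d(model: SwinUNet2D, slices) -> Tensor:
    """Per-pixel class probabilities for a batch of axial slices.

    Accepts (H, W), (N, H, W) or (N, 1, H, W); returns probabilities with
    a leading class axis, batched iff the input was.
    """
    x, batched = _prep(slices, model.cfg.input_size, 2)
    probs = ad.softmax(model(x), axis=1)
    return probs if batched else probs.reshape(*probs.shape[1:])


def forward_3d(model: UNet3D, patches) -> Tensor:
    """Per-voxel class probabilities for a batch of patches.

    Accepts (X, Y, Z), (N, X, Y, Z) or (N, 1, X, Y, Z).
    """
    x, batched = _prep(patches, model.cfg.input_size, 3)
    probs = ad.softmax(model(x), axis=1)
    return probs if batched else probs.reshape(*probs.shape[1:])


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------


def checkpoint_id(model: nn.Module) -> str:
    """Stable content hash of the model weights + config."""
    h = hashlib.sha256()
    h.update(json.dumps(asdict(model.cfg), sort_keys=True, default=list).encode())
    for name, p in sorted(model.named_parameters()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()[:16]


def save_checkpoint(model: nn.Module, path, seed: int | None = None) -> str:
    """Write weights + full config (+ seed) to an .npz; return checkpoint id."""
    meta = {
        "kind": type(model).__name__,
        "config": asdict(model.cfg),
        "seed": seed,
        "checkpoint_id": checkpoint_id(model),
    }
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return meta["checkpoint_id"]


def load_checkpoint(path):
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    cfg_d = meta["config"]
    if meta["kind"] == "SwinUNet2D":
        cfg = Net2DConfig(**{**cfg_d, "depths": tuple(cfg_d["depths"]),
                             "n_heads": tuple(cfg_d["n_heads"]),
                             "input_size": tuple(cfg_d["input_size"])})
        model = SwinUNet2D(cfg)
    elif meta["kind"] == "UNet3D":
        cfg = Net3DConfig(**{**cfg_d, "input_size": tuple(cfg_d["input_size"])})
        model = UNet3D(cfg)
    else:
        raise ValueError(f"unknown checkpoint kind {meta['kind']!r}")
    model.load_state_dict(state)
    model.eval()
    return model, meta
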