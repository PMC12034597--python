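"""Sliding-window patch extraction, axial slice (de)composition and
overlap-aware stitching of patch probability maps.

Origin lattice: per axis the origins are {0, s, 2s, ...} plus a final
origin clamped to ``dim - w`` whenever the lattice does not already end
there, so every voxel is covered without padding.  Volumes smaller than
the window are zero-padded up to the window (the label/probability
extent is cropped back after stitching).  Patch order is deterministic:
z-major, then y, then x.

Overlapping patch probabilities are fused by arithmetic mean before any
argmax; argmax ties break toward the lower class index (background).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import Volume

__all__ = [
    "Patch",
    "SliceStack",
    "StitchAccumulator",
    "axis_origins",
    "crop_patches",
    "get_slices",
    "merge_slices",
    "stitch",
    "CoverageError",
]


class CoverageError(ValueError):
    """Raised when stitched patches do not cover the whole volume."""


@dataclass
class Patch:
    data: np.ndarray
    origin: tuple[int, int, int]
    case_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("patch data must be 3D")
        self.origin = tuple(int(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SliceStack:
    slices: list[np.ndarray]
    z_offsets: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.z_offsets:
            self.z_offsets = list(range(len(self.slices)))
        if len(self.z_offsets) != len(self.slices):
            raise ValueError("z_offsets must pair 1:1 with slices")


def axis_origins(dim: int, window: int, stride: int) -> list[int]:
    """Sliding-window origins along one axis with a clamped final origin."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if stride > window:
        raise ValueError("stride must not exceed window (coverage would have gaps)")
    if window >= dim:
        return [0]
    origins = list(range(0, dim - window + 1, stride))
    if origins[-1] != dim - window:
        origins.append(dim - window)
    return origins


def _pad_to_window(grid: np.ndarray, window) -> np.ndarray:
    padw = [(0, max(0, w - n)) for n, w in zip(grid.shape, window)]
    if any(p[1] for p in padw):
        grid = np.pad(grid, padw)
    return grid


def crop_patches(
    v: Volume | np.ndarray,
    window: tuple[int, int, int],
    stride: tuple[int, int, int],
) -> list[Patch]:
    """Crop the full sliding-window lattice of patches from a volume.

    Order is z-major, then y, then x (z varies slowest).
    """
    grid = v.intensities if isinstance(v, Volume) else np.asarray(v)
    case_id = v.case_id if isinstance(v, Volume) else ""
    if grid.ndim != 3:
        raise ValueError("expected a 3D grid")
    grid = _pad_to_window(grid, window)
    ox = axis_origins(grid.shape[0], window[0], stride[0])
    oy = axis_origins(grid.shape[1], window[1], stride[1])
    oz = axis_origins(grid.shape[2], window[2], stride[2])
    patches = []
    for z in oz:
        for y in oy:
            for x in ox:
                sub = grid[x:x + window[0], y:y + window[1], z:z + window[2]]
                patches.append(Patch(sub.copy(), (x, y, z), case_id))
    return patches


def get_slices(p: Patch) -> SliceStack:
    """Split a patch into its axial slices (z planes)."""
    wz = p.data.shape[2]
    return SliceStack([p.data[:, :, k].copy() for k in range(wz)], list(range(wz)))


def merge_slices(s: SliceStack) -> np.ndarray:
    """Stack 2D slices back into a 3D grid, honouring z_offsets."""
    shapes = {sl.shape for sl in s.slices}
    if len(shapes) != 1:
        raise ValueError(f"ragged slice shapes: {sorted(shapes)}")
    order = np.argsort(s.z_offsets)
    return np.stack([np.asarray(s.slices[i]) for i in order], axis=2)


def stitch(
    patch_probs: list[tuple[tuple[int, int, int], np.ndarray]],
    volume_shape: tuple[int, int, int],
) -> np.ndarray:
    """Fuse per-patch probability maps into a full-volume probability map.

    `patch_probs` holds (origin, probs) pairs with probs shaped
    (classes, wx, wy, wz).  Each voxel's probability is the arithmetic
    mean over all contributing patches, renormalized to sum to 1.
    Raises :class:`CoverageError` if any voxel is uncovered.
    """
    if not patch_probs:
        raise CoverageError("no patches to stitch")
    n_classes = {p.shape[0] for _, p in patch_probs}
    if len(n_classes) != 1:
        raise ValueError("all patch probability maps must share a class count")
    c = n_classes.pop()
    # accumulate on the padded extent so clamped/padded patches fit
    ext = [max(volume_shape[i], max(o[i] + p.shape[1 + i] for o, p in patch_probs))
           for i in range(3)]
    prob_sum = np.zeros((c, *ext), dtype=np.float64)
    count = np.zeros(ext, dtype=np.int32)
    for origin, probs in patch_probs:
        probs = np.asarray(probs)
        ox, oy, oz = origin
        wx, wy, wz = probs.shape[1:]
        prob_sum[:, ox:ox + wx, oy:oy + wy, oz:oz + wz] += probs
        count[ox:ox + wx, oy:oy + wy, oz:oz + wz] += 1
    core = tuple(slice(0, n) for n in volume_shape)
    if (count[core] == 0).any():
        gap = np.argwhere(count[core] == 0)
        lo, hi = gap.min(axis=0), gap.max(axis=0)
        raise CoverageError(
            f"uncovered voxels in region {tuple(lo)}..{tuple(hi)}"
        )
    mean = prob_sum[(slice(None),) + core] / count[core]
    total = mean.sum(axis=0)
    return mean / np.where(total > 0, total, 1.0)
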