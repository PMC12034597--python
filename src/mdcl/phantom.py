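"""Synthetic tubular phantoms emulating the structure of an abdominal
CT segmentation cohort.

Each phantom contains a foreground made of one or more smooth random
tubes (a cubic-spline-smoothed 3D random walk dilated by a Euclidean
ball of sampled radius) — a cheap, controllable stand-in for folded
bowel — plus ellipsoidal confounder blobs whose intensity lies within
±10% of the tube intensity but whose label is background, emulating
contact with neighbouring organs of similar attenuation.  Additive
Gaussian intensity noise is applied last, so changing only ``noise_sd``
changes intensities but never labels.

The generator resamples until the foreground fraction falls in a
configurable band (default 1–15% of voxels), keeping the class
imbalance comparable to the clinical setting.  Everything is a pure
function of ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .volume_io import Cohort, LabelMask, Volume

__all__ = ["PhantomSpec", "make_phantom", "sparsify_labels", "make_cohort", "PhantomGeometryError"]


class PhantomGeometryError(RuntimeError):
    """Raised when no feasible phantom exists under the spec's constraints."""


@dataclass(frozen=True)
class PhantomSpec:
    grid_size: tuple[int, int, int] = (64, 64, 32)
    n_tubes: int = 2
    tube_radius_range: tuple[float, float] = (2.0, 4.0)
    tube_intensity: float = 1.0
    background_intensity: float = 0.0
    n_confounders: int = 2
    noise_sd: float = 0.05
    seed: int = 0
    fg_fraction_range: tuple[float, float] = (0.01, 0.15)
    max_retries: int = 20

    def __post_init__(self):
        if min(self.grid_size) < 16:
            raise ValueError("grid_size components must be >= 16")
        rmin, rmax = self.tube_radius_range
        if not (0 < rmin <= rmax) or 2 * rmax >= min(self.grid_size):
            raise ValueError("tube radius range must be positive and fit the grid")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _tube_centerline(rng: np.random.Generator, shape, radius: float) -> np.ndarray:
    """Smoothed random-walk centerline as dense points, kept `radius`
    inside the grid boundary."""
    shape = np.asarray(shape, dtype=float)
    margin = radius + 1.0
    lo, hi = margin, shape - 1 - margin
    n_ctrl = 8
    step = float(shape.min()) / 3.0
    pts = [rng.uniform(lo, hi)]
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    for _ in range(n_ctrl - 1):
        direction = direction + 0.6 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        nxt = np.clip(pts[-1] + direction * step, lo, hi)
        pts.append(nxt)
    pts = np.asarray(pts)
    t = np.linspace(0.0, 1.0, n_ctrl)
    spline = CubicSpline(t, pts, axis=0)
    # dense sampling: step << 1 voxel so the dilated tube is connected
    dense = spline(np.linspace(0.0, 1.0, int(40 * n_ctrl)))
    return np.clip(dense, lo, hi)


def _rasterize_tubes(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    shape = spec.grid_size
    labels = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_tubes):
        radius = rng.uniform(*spec.tube_radius_range)
        line = _tube_centerline(rng, shape, radius)
        center_mask = np.zeros(shape, dtype=bool)
        idx = np.round(line).astype(int)
        idx = np.clip(idx, 0, np.asarray(shape) - 1)
        center_mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        dist = ndimage.distance_transform_edt(~center_mask)
        labels |= dist <= radius  # Euclidean ball dilation
    return labels


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMask]:
    """Generate one phantom volume and its dense label mask."""
    master = np.random.default_rng(spec.seed)
    lo, hi = spec.fg_fraction_range
    labels = None
    for _ in range(spec.max_retries):
        rng = np.random.default_rng(master.integers(2**31))
        cand = _rasterize_tubes(rng, spec)
        frac = cand.mean()
        if lo <= frac <= hi:
            labels = cand
            break
    if labels is None:
        raise PhantomGeometryError(
            f"could not draw a phantom with foreground fraction in "
            f"[{lo}, {hi}] after {spec.max_retries} retries (grid "
            f"{spec.grid_size}, {spec.n_tubes} tubes, radii "
            f"{spec.tube_radius_range})"
        )

    intensities = np.full(spec.grid_size, spec.background_intensity, dtype=np.float32)
    intensities[labels] = spec.tube_intensity

    # confounders: intensity within ±10% of the tubes, labels stay 0;
    # the first one is anchored next to a tube surface so it touches
    if spec.n_confounders > 0:
        surface = labels & ~ndimage.binary_erosion(labels)
        surf_idx = np.argwhere(surface)
        for i in range(spec.n_confounders):
            semi = rng.uniform(2.0, 5.0, size=3)
            if i == 0 and len(surf_idx):
                anchor = surf_idx[rng.integers(len(surf_idx))]
                offset = rng.normal(size=3)
                offset /= np.linalg.norm(offset)
                center = anchor + offset * semi * 0.8
            else:
                center = rng.uniform(0, np.asarray(spec.grid_size) - 1)
            center = np.clip(center, 0, np.asarray(spec.grid_size) - 1)
            blob = _ellipsoid_mask(spec.grid_size, center, semi)
            level = spec.tube_intensity * rng.uniform(0.9, 1.1)
            intensities[blob & ~labels] = level

    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng(np.random.default_rng(spec.seed ^ 0x5EED).integers(2**31))
        intensities = intensities + noise_rng.normal(0.0, spec.noise_sd, size=spec.grid_size).astype(np.float32)

    vol = Volume(intensities.astype(np.float32), (1.0, 1.0, 1.0), case_id=f"phantom{spec.seed}")
    return vol, LabelMask.dense(labels.astype(np.uint8))


def sparsify_labels(
    m: LabelMask, fraction: float, seed: int, within_foreground: bool = False
) -> LabelMask:
    """Keep a uniformly sampled subset of labeled axial slices.

    The label grid itself is unchanged; only the bookkeeping of which
    slices count as ground truth shrinks, mirroring sparsely annotated
    clinical volumes.  With ``within_foreground`` the subset is drawn
    preferentially from slices that intersect the structure — the way
    annotators pick slices to label — falling back to the remaining
    planes only when too few foreground-bearing slices exist.
    """
    if m.density != "dense":
        raise ValueError("sparsify_labels expects a densely labeled mask")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    nz = m.shape[2]
    k = max(1, int(np.floor(fraction * nz + 0.5)))
    rng = np.random.default_rng(seed)
    if within_foreground:
        fg_z = np.flatnonzero(m.labels.sum(axis=(0, 1)) > 0)
        bg_z = np.setdiff1d(np.arange(nz), fg_z)
        take_fg = min(k, len(fg_z))
        keep = list(rng.choice(fg_z, size=take_fg, replace=False))
        if k > take_fg:
            keep += list(rng.choice(bg_z, size=k - take_fg, replace=False))
        keep = np.asarray(keep)
    else:
        keep = rng.choice(nz, size=k, replace=False)
    return LabelMask(m.labels.copy(), frozenset(int(z) for z in keep), "sparse")


def make_cohort(
    n_labeled: int,
    n_unlabeled: int,
    n_val: int,
    n_test: int,
    spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
    eval_density: str = "sparse",
    sparse_fraction: float = 0.1,
) -> Cohort:
    """Draw a full cohort of independent phantoms.

    Per-case seeds are spawned from the master seed with a splittable
    seed sequence, so individual cases are stable regardless of how many
    cases surround them in each list.
    """
    if min(n_labeled, n_unlabeled, n_val, n_test) < 0:
        raise ValueError("cohort counts must be >= 0")
    groups = {"lab": n_labeled, "unl": n_unlabeled, "val": n_val, "tst": n_test}
    streams = {
        name: np.random.SeedSequence(seed, spawn_key=(gi,)).spawn(n)
        for gi, (name, n) in enumerate(groups.items())
    }

    def case(name: str, i: int) -> tuple[Volume, LabelMask]:
        child_seed = int(streams[name][i].generate_state(1)[0] % (2**31))
        v, m = make_phantom(replace(spec, seed=child_seed))
        v.case_id = f"{name}{i:03d}"
        return v, m, child_seed

    labeled = []
    for i in range(n_labeled):
        v, m, _ = case("lab", i)
        labeled.append((v, m))
    unlabeled = [case("unl", i)[0] for i in range(n_unlabeled)]

    def eval_case(name: str, i: int):
        v, m, s = case(name, i)
        if eval_density == "sparse":
            m = sparsify_labels(m, sparse_fraction, seed=s + 1, within_foreground=True)
        return v, m

    validation = [eval_case("val", i) for i in range(n_val)]
    test = [eval_case("tst", i) for i in range(n_test)]
    return Cohort(labeled, unlabeled, validation, test)
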