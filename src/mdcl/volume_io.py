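"""Volumes, label masks and cohort structure, with NIfTI I/O.

Conventions used throughout the package:

* grids are indexed ``(x, y, z)`` with ``z`` the axial (head-foot)
  direction; every slice operation acts along ``z``;
* indices are 0-based, ranges half-open;
* labels are binary: 0 = background, 1 = intestine (foreground).

A label mask records *which* axial slices carry ground truth explicitly
(``labeled_slices``) rather than inferring it from all-zero planes,
because a genuinely labeled slice may contain no foreground.  Masks are
written as NIfTI next to a small sidecar JSON holding ``case_id``,
``density`` and ``labeled_slices``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "LabelMask",
    "Cohort",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "save_cohort",
    "load_cohort",
    "resample_isotropic",
    "restrict_to_labeled_slices",
    "MalformedVolumeError",
]


class MalformedVolumeError(ValueError):
    """Raised for unreadable, malformed or non-3D NIfTI inputs."""


@dataclass
class Volume:
    """A 3D intensity grid with voxel spacing in mm."""

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    case_id: str = ""

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or min(self.intensities.shape) < 1:
            raise MalformedVolumeError("non-3D input: volume grid must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class LabelMask:
    """Binary labels plus the set of axial slices carrying ground truth."""

    labels: np.ndarray
    labeled_slices: frozenset[int] = field(default_factory=frozenset)
    density: str = "dense"

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise MalformedVolumeError("non-3D input: label grid must be 3D")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary {0, 1}")
        self.labels = self.labels.astype(np.uint8)
        if self.density not in ("dense", "sparse", "unlabeled"):
            raise ValueError(f"unknown density {self.density!r}")
        nz = self.labels.shape[2]
        self.labeled_slices = frozenset(int(z) for z in self.labeled_slices)
        if any(z < 0 or z >= nz for z in self.labeled_slices):
            raise ValueError("labeled_slices outside valid z range")
        if self.density == "unlabeled" and self.labeled_slices:
            raise ValueError("unlabeled mask cannot have labeled slices")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @classmethod
    def dense(cls, labels: np.ndarray) -> "LabelMask":
        labels = np.asarray(labels)
        return cls(labels, frozenset(range(labels.shape[2])), "dense")


@dataclass
class Cohort:
    """Case-level split: densely labeled and unlabeled training volumes,
    plus validation and test volumes with (possibly sparse) masks."""

    labeled: list[tuple[Volume, LabelMask]]
    unlabeled: list[Volume]
    validation: list[tuple[Volume, LabelMask]]
    test: list[tuple[Volume, LabelMask]]

    def __post_init__(self):
        ids = self.case_ids()
        if len(ids) != len(set(ids)):
            raise ValueError("case_ids must be disjoint across cohort lists")

    def case_ids(self) -> list[str]:
        out = [v.case_id for v, _ in self.labeled]
        out += [v.case_id for v in self.unlabeled]
        out += [v.case_id for v, _ in self.validation]
        out += [v.case_id for v, _ in self.test]
        return out


# --------------------------------------------------------------------------
# NIfTI I/O
# --------------------------------------------------------------------------


def write_volume(v: Volume, path) -> None:
    affine = np.diag(list(v.spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(v.intensities), affine), str(path))


def read_volume(path) -> Volume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises various header errors
        raise MalformedVolumeError(f"malformed NIfTI header in {path}: {exc}") from exc
    if data.ndim != 3:
        raise MalformedVolumeError(f"non-3D input: {path} has {data.ndim} dimensions")
    return Volume(data, tuple(float(z) for z in zooms[:3]), case_id=path.name.split(".")[0])


def write_mask(m: LabelMask, path, case_id: str = "") -> None:
    """NIfTI labels + sidecar JSON ``<stem>.json`` with the mask metadata."""
    path = Path(path)
    nib.save(nib.Nifti1Image(m.labels.astype(np.uint8), np.eye(4)), str(path))
    sidecar = path.parent / (path.name.split(".")[0] + ".json")
    sidecar.write_text(json.dumps({
        "case_id": case_id,
        "density": m.density,
        "labeled_slices": sorted(m.labeled_slices),
    }))


def read_mask(path) -> LabelMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask file: {path}")
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    if labels.ndim != 3:
        raise MalformedVolumeError(f"non-3D input: {path}")
    sidecar = path.parent / (path.name.split(".")[0] + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        return LabelMask(labels, frozenset(meta["labeled_slices"]), meta["density"])
    return LabelMask.dense(labels)


def save_cohort(cohort: Cohort, directory) -> None:
    """Write a cohort as NIfTI files + sidecars under
    ``<dir>/{labeled,unlabeled,validation,test}/``."""
    root = Path(directory)
    for sub, items in (("labeled", cohort.labeled), ("validation", cohort.validation),
                       ("test", cohort.test)):
        d = root / sub
        d.mkdir(parents=True, exist_ok=True)
        for v, m in items:
            write_volume(v, d / f"{v.case_id}_img.nii.gz")
            write_mask(m, d / f"{v.case_id}_msk.nii.gz", case_id=v.case_id)
    d = root / "unlabeled"
    d.mkdir(parents=True, exist_ok=True)
    for v in cohort.unlabeled:
        write_volume(v, d / f"{v.case_id}_img.nii.gz")


def load_cohort(directory) -> Cohort:
    root = Path(directory)

    def pairs(sub):
        out = []
        for f in sorted((root / sub).glob("*_img.nii.gz")):
            v = read_volume(f)
            v.case_id = f.name[: -len("_img.nii.gz")]
            m = read_mask(f.parent / f"{v.case_id}_msk.nii.gz")
            out.append((v, m))
        return out

    unlabeled = []
    for f in sorted((root / "unlabeled").glob("*_img.nii.gz")):
        v = read_volume(f)
        v.case_id = f.name[: -len("_img.nii.gz")]
        unlabeled.append(v)
    return Cohort(pairs("labeled"), unlabeled, pairs("validation"), pairs("test"))


# --------------------------------------------------------------------------
# resampling and slice restriction
# --------------------------------------------------------------------------


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def resample_isotropic(
    v: Volume,
    m: LabelMask | None = None,
    target_mm: float = 1.0,
) -> tuple[Volume, LabelMask | None]:
    """Resample to isotropic ``target_mm`` voxels.

    Intensities are linearly interpolated, labels with nearest neighbour
    so they stay binary.  Output grid dimension per axis is
    ``round(dim * spacing / target_mm)`` with round-half-away-from-zero,
    so dimension arithmetic is exact and testable.  Already-isotropic
    inputs at the target spacing pass through unchanged.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    in_shape = np.array(v.shape, dtype=float)
    spacing = np.array(v.spacing, dtype=float)
    out_shape = _round_half_away(in_shape * spacing / target_mm).astype(int)
    out_shape = np.maximum(out_shape, 1)
    new_spacing = (float(target_mm),) * 3

    if tuple(out_shape) == v.shape and np.allclose(spacing, target_mm):
        return Volume(v.intensities.copy(), new_spacing, v.case_id), (
            LabelMask(m.labels.copy(), m.labeled_slices, m.density) if m is not None else None
        )

    # index-aligned mapping: output index j samples input coordinate
    # j * target_mm / spacing along each axis
    coords = np.meshgrid(
        *[np.arange(n) * target_mm / s for n, s in zip(out_shape, spacing)],
        indexing="ij",
    )
    coords = np.stack(coords)
    out_int = ndimage.map_coordinates(
        v.intensities.astype(float), coords, order=1, mode="nearest"
    )
    new_v = Volume(out_int, new_spacing, v.case_id)
    if m is None:
        return new_v, None
    if m.shape != v.shape:
        raise ValueError("mask shape must equal volume shape")
    out_lab = ndimage.map_coordinates(m.labels, coords, order=0, mode="nearest")
    # map labeled slice indices to the new z grid (nearest output plane)
    sz = spacing[2]
    new_nz = int(out_shape[2])
    new_slices = {
        int(np.clip(_round_half_away(np.array(z * sz / target_mm)), 0, new_nz - 1))
        for z in m.labeled_slices
    }
    if m.density == "dense":
        new_slices = set(range(new_nz)) if len(m.labeled_slices) == v.shape[2] else new_slices
    new_m = LabelMask(out_lab, frozenset(new_slices), m.density)
    return new_v, new_m


def restrict_to_labeled_slices(
    m: LabelMask, prediction: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pair ground truth and prediction voxels on labeled slices only.

    Returns flat (ground_truth, prediction) arrays covering every voxel
    whose z index is labeled, ordered by ascending z then C-order within
    each slice.  An empty ``labeled_slices`` yields empty arrays.
    """
    prediction = np.asarray(prediction)
    if prediction.shape != m.shape:
        raise ValueError(
            f"prediction shape {prediction.shape} != labels shape {m.shape}"
        )
    zs = sorted(m.labeled_slices)
    if not zs:
        return np.empty(0, dtype=m.labels.dtype), np.empty(0, dtype=prediction.dtype)
    gt = np.concatenate([m.labels[:, :, z].ravel() for z in zs])
    pr = np.concatenate([prediction[:, :, z].ravel() for z in zs])
    return gt, pr
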