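"""Pseudo-label generation for unlabeled patches.

A trained 2D network labels each unlabeled 3D patch by slicing it into
axial planes, inferring every plane, merging the per-slice probability
maps back into a patch-shaped probability grid and taking the per-voxel
argmax (ties break to background).  Pseudo-labels are computed once
after step-1 training, frozen, and cached on disk keyed by
(case_id, patch origin, checkpoint id), which decouples the two
training steps and makes regeneration a no-op for an unchanged
checkpoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from . import models
from .patching import Patch, SliceStack, get_slices, merge_slices
from .models import SwinUNet2D, forward_2d

__all__ = ["PseudoLabel", "pseudo_label_patch", "pseudo_label_cohort", "PseudoLabelCache"]


@dataclass
class PseudoLabel:
    labels: np.ndarray
    source_checkpoint: str
    origin: tuple[int, int, int]
    case_id: str

    def __post_init__(self):
        self.labels = np.asarray(self.labels).astype(np.uint8)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("pseudo-labels must be binary")


def pseudo_label_patch(model2d: SwinUNet2D, p: Patch, checkpoint: str | None = None) -> PseudoLabel:
    """argmax(merge_slices(forward_2d(get_slices(patch))))."""
    if model2d.training:
        raise RuntimeError("pseudo-labeling requires the model in evaluation mode")
    stack = get_slices(p)
    batch = np.stack(stack.slices)                     # (wz, wx, wy)
    probs = forward_2d(model2d, batch).data            # (wz, C, wx, wy)
    # merge each class's per-slice maps back into (wx, wy, wz)
    merged = np.stack([
        merge_slices(SliceStack([probs[k, c] for k in range(probs.shape[0])],
                                list(stack.z_offsets)))
        for c in range(probs.shape[1])
    ])                                                 # (C, wx, wy, wz)
    labels = np.argmax(merged, axis=0).astype(np.uint8)  # ties -> class 0
    ckpt = checkpoint or models.checkpoint_id(model2d)
    return PseudoLabel(labels, ckpt, p.origin, p.case_id)


class PseudoLabelCache:
    """On-disk cache of pseudo-labels: NIfTI fragments + a JSON manifest."""

    def __init__(self, directory):
        self.dir = Path(directory)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.dir / "manifest.json"
        self.manifest: dict[str, str] = (
            json.loads(self.manifest_path.read_text()) if self.manifest_path.exists() else {}
        )

    @staticmethod
    def key(case_id: str, origin, checkpoint: str) -> str:
        return f"{case_id}|{origin[0]},{origin[1]},{origin[2]}|{checkpoint}"

    def get(self, case_id: str, origin, checkpoint: str) -> PseudoLabel | None:
        k = self.key(case_id, origin, checkpoint)
        fname = self.manifest.get(k)
        if fname is None:
            return None
        labels = np.asarray(nib.load(str(self.dir / fname)).dataobj)
        return PseudoLabel(labels, checkpoint, tuple(origin), case_id)

    def put(self, pl: PseudoLabel) -> None:
        k = self.key(pl.case_id, pl.origin, pl.source_checkpoint)
        fname = f"pl_{len(self.manifest):05d}.nii.gz"
        nib.save(nib.Nifti1Image(pl.labels, np.eye(4)), str(self.dir / fname))
        self.manifest[k] = fname
        self.manifest_path.write_text(json.dumps(self.manifest, indent=0))

    def __len__(self) -> int:
        return len(self.manifest)


def pseudo_label_cohort(
    model2d: SwinUNet2D,
    unlabeled_patches: list[Patch],
    cache: PseudoLabelCache | None = None,
) -> dict[str, PseudoLabel]:
    """Pseudo-label every unlabeled patch, reusing cached results.

    Returns a mapping ``"case|ox,oy,oz|ckpt" -> PseudoLabel``.  A cache
    hit is returned without recomputation; changing the checkpoint
    invalidates every key.
    """
    if model2d.training:
        raise RuntimeError("pseudo-labeling requires the model in evaluation mode")
    ckpt = models.checkpoint_id(model2d)
    out: dict[str, PseudoLabel] = {}
    missing: list[Patch] = []
    for p in unlabeled_patches:
        k = PseudoLabelCache.key(p.case_id, p.origin, ckpt)
        pl = cache.get(p.case_id, p.origin, ckpt) if cache is not None else None
        if pl is None:
            missing.append(p)
        else:
            out[k] = pl
    # batch several patches' slices through one forward pass; per-sample
    # normalization makes this voxel-identical to patch-at-a-time inference
    group = max(1, 64 // max(p.data.shape[2] for p in missing)) if missing else 1
    for i in range(0, len(missing), group):
        chunk = missing[i:i + group]
        stacks = [get_slices(p) for p in chunk]
        batch = np.concatenate([np.stack(s.slices) for s in stacks])
        probs = forward_2d(model2d, batch).data
        offset = 0
        for p, stack in zip(chunk, stacks):
            wz = len(stack.slices)
            pp = probs[offset:offset + wz]
            offset += wz
            merged = np.stack([
                merge_slices(SliceStack([pp[k, c] for k in range(wz)], list(stack.z_offsets)))
                for c in range(pp.shape[1])
            ])
            pl = PseudoLabel(np.argmax(merged, axis=0).astype(np.uint8), ckpt,
                             p.origin, p.case_id)
            if cache is not None:
                cache.put(pl)
            out[PseudoLabelCache.key(p.case_id, p.origin, ckpt)] = pl
    return out
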