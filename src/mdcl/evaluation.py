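"""Whole-volume inference, segmentation metrics under the sparse-slice
rule, multi-seed aggregation and the paired Wilcoxon signed-rank test.

Metric conventions (binary foreground): Dice = 2TP/(2TP+FP+FN),
precision = TP/(TP+FP), recall = TP/(TP+FN).  When both ground truth
and prediction are empty all three are defined as 1 (a sparse labeled
slice can legitimately contain no foreground); an empty denominator
facing a non-empty counterpart yields 0.

For sparsely labeled volumes every metric is computed only on the
labeled axial slices; predictions elsewhere never influence the result.
Experiments are repeated over seeds, per-case values averaged across
seeds first, then mean +/- SD taken across cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import models
from .patching import crop_patches, stitch
from .volume_io import LabelMask, Volume, restrict_to_labeled_slices

__all__ = [
    "MetricsReport",
    "infer_volume",
    "seg_metrics",
    "evaluate_case",
    "aggregate_seeds",
    "wilcoxon_signed_rank",
]

METRICS = ("dice", "precision", "recall")


@dataclass
class MetricsReport:
    per_case: dict[str, dict[str, float]]
    mean: dict[str, float]
    sd: dict[str, float]
    n_cases: int
    seeds: tuple[int, ...] = field(default_factory=tuple)


def infer_volume(
    model3d: models.UNet3D,
    v: Volume,
    window: tuple[int, int, int] | None = None,
    stride: tuple[int, int, int] | None = None,
    batch_size: int = 4,
) -> np.ndarray:
    """Segment a whole volume: crop -> 3D forward -> stitch -> argmax."""
    if model3d.training:
        raise RuntimeError("inference requires the model in evaluation mode")
    window = tuple(window or model3d.cfg.input_size)
    stride = tuple(stride or (max(1, w // 2) for w in window))
    patches = crop_patches(v, window, stride)
    pairs = []
    for i in range(0, len(patches), batch_size):
        chunk = patches[i:i + batch_size]
        batch = np.stack([p.data for p in chunk]).astype(np.float32)
        probs = models.forward_3d(model3d, batch).data
        pairs.extend((p.origin, probs[j]) for j, p in enumerate(chunk))
    grid = v.intensities if isinstance(v, Volume) else np.asarray(v)
    fused = stitch(pairs, grid.shape)
    return np.argmax(fused, axis=0).astype(np.uint8)  # ties -> background


def seg_metrics(gt, pred) -> tuple[float, float, float]:
    """(dice, precision, recall) from flat binary label arrays."""
    gt = np.asarray(gt).ravel()
    pred = np.asarray(pred).ravel()
    if gt.shape != pred.shape:
        raise ValueError(f"length mismatch: {gt.shape} vs {pred.shape}")
    if gt.size and (not np.isin(gt, (0, 1)).all() or not np.isin(pred, (0, 1)).all()):
        raise ValueError("labels must be binary")
    tp = int(np.sum((gt == 1) & (pred == 1)))
    fp = int(np.sum((gt == 0) & (pred == 1)))
    fn = int(np.sum((gt == 1) & (pred == 0)))
    dice = 1.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
    precision = (1.0 if fn == 0 else 0.0) if (tp + fp) == 0 else tp / (tp + fp)
    recall = (1.0 if fp == 0 else 0.0) if (tp + fn) == 0 else tp / (tp + fn)
    return dice, precision, recall


def evaluate_case(
    model3d: models.UNet3D,
    v: Volume,
    m: LabelMask,
    window: tuple[int, int, int] | None = None,
    stride: tuple[int, int, int] | None = None,
) -> dict[str, float]:
    """Per-case metrics restricted to labeled slices."""
    pred = infer_volume(model3d, v, window, stride)
    gt_flat, pred_flat = restrict_to_labeled_slices(m, pred)
    d, p, r = seg_metrics(gt_flat, pred_flat)
    return {"dice": d, "precision": p, "recall": r}


def metrics_from_prediction(m: LabelMask, pred: np.ndarray) -> dict[str, float]:
    """Metrics for an already-computed prediction, sparse-slice rule applied."""
    gt_flat, pred_flat = restrict_to_labeled_slices(m, pred)
    d, p, r = seg_metrics(gt_flat, pred_flat)
    return {"dice": d, "precision": p, "recall": r}


def aggregate_seeds(
    per_seed: dict[int, dict[str, dict[str, float]]],
) -> MetricsReport:
    """Average per-case metrics over seeds, then mean +/- SD across cases.

    ``per_seed`` maps seed -> case_id -> metric -> value; every seed
    must cover the same cases.
    """
    seeds = tuple(sorted(per_seed))
    if not seeds:
        raise ValueError("no seeds to aggregate")
    case_sets = [set(v) for v in per_seed.values()]
    if any(cs != case_sets[0] for cs in case_sets):
        raise ValueError("all seeds must report the same cases")
    cases = sorted(case_sets[0])
    per_case = {
        cid: {
            met: float(np.mean([per_seed[s][cid][met] for s in seeds]))
            for met in METRICS
        }
        for cid in cases
    }
    mean = {met: float(np.mean([per_case[c][met] for c in cases])) for met in METRICS}
    sd = {met: float(np.std([per_case[c][met] for c in cases])) for met in METRICS}
    return MetricsReport(per_case, mean, sd, len(cases), seeds)


def wilcoxon_signed_rank(a, b) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (Wilcoxon's original procedure); the
    null distribution is enumerated exactly for n <= 12 untied
    differences and approximated normally (with tie correction)
    otherwise.  If every difference is zero the test is degenerate and
    p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    if d.size < 5:
        raise ValueError("need >= 5 nonzero differences for the signed-rank test")
    ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 12 and not ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.pvalue)
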