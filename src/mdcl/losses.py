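"""Loss algebra of the two-step pipeline.

The supervised loss is a convex combination of cross-entropy and soft
(foreground) Dice,

    L_sup = alpha * L_ce + (1 - alpha) * L_dice,        alpha = 0.3,

used for both networks on labeled data.  Unlabeled patches contribute a
Dice-only consistency term against the frozen pseudo-labels,

    L_un = L_dice(P_3d, P*),      L_total = L_sup + L_un  (unit weights),

Dice-only because the foreground/background imbalance of tubular
structures makes cross-entropy on noisy pseudo-labels unstable.

All losses consume class *probabilities* (never logits or argmaxed
maps), accept either autodiff tensors or plain arrays, and return 0-d
:class:`~mdcl.autodiff.Tensor` values so gradients flow to the network
but never into the (constant) targets.

Conventions: soft Dice is computed per batch item and then averaged;
the smoothing constant handles empty foreground (empty/empty -> loss 0);
probabilities are floored at ``CE_FLOOR`` before the log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, as_tensor

__all__ = [
    "LossWeights",
    "LossReport",
    "ce_loss",
    "dice_loss",
    "supervised_loss",
    "unsupervised_loss",
    "total_loss",
    "CE_FLOOR",
]

CE_FLOOR = 1e-12  # probability floor before taking the log


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 0.3
    dice_smooth: float = 1e-5

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.dice_smooth <= 0:
            raise ValueError("dice_smooth must be positive")


@dataclass
class LossReport:
    """Scalar loss values of one optimization step (floats)."""

    l_ce: float
    l_dice: float
    l_sup: float
    l_un: float = 0.0
    l_total: float = field(default=np.nan)

    def __post_init__(self):
        if np.isnan(self.l_total):
            self.l_total = self.l_sup + self.l_un


def _batched(pred, target_shape, batched):
    """Resolve whether pred is (N, C, *spatial) for target (N, *spatial).

    With 2 classes a (2, *sp) prediction is indistinguishable from a
    batch of two, so callers may pass `batched` explicitly; automatic
    detection prefers the batched layout.
    """
    ps = tuple(pred.shape)
    ts = tuple(target_shape)
    if len(ps) != len(ts) + 1:
        raise ValueError(f"prediction shape {ps} incompatible with target {ts}")
    fits_batched = ps[0] == ts[0] and ps[2:] == ts[1:]
    fits_single = ps[1:] == ts
    if batched is None:
        batched = fits_batched
    if (batched and not fits_batched) or (not batched and not fits_single):
        raise ValueError(f"prediction shape {ps} incompatible with target {ts}")
    return batched


def _as_batch(pred, target, batched):
    """Normalize to pred (N, C, *sp) tensor and target (N, *sp) int array."""
    pred = as_tensor(pred)
    target = np.asarray(target)
    if target.ndim == pred.ndim:
        # one-hot target: only the unambiguous batched layout (N, C, *sp)
        if target.shape != tuple(pred.shape) or target.ndim < 4:
            raise ValueError("one-hot targets must be batched and match pred shape")
        target = np.argmax(target, axis=1)
    if not _batched(pred, target.shape, batched):
        pred = pred.reshape(1, *pred.shape)
        target = target[None]
    return pred, target.astype(np.int64)


def _onehot(target: np.ndarray, n_classes: int, dtype) -> np.ndarray:
    eye = np.eye(n_classes, dtype=dtype)
    oh = eye[target]  # (N, *sp, C)
    return np.moveaxis(oh, -1, 1)


def ce_loss(pred, target, batched: bool | None = None) -> Tensor:
    """Mean over elements of -log p(target class)."""
    pred, target = _as_batch(pred, target, batched)
    n_classes = pred.shape[1]
    if target.min() < 0 or target.max() >= n_classes:
        raise ValueError("target values outside {0..n_classes-1}")
    oh = _onehot(target, n_classes, pred.dtype)
    p_t = (pred * oh).sum(axis=1)
    return -(ad.log(ad.clip_min(p_t, CE_FLOOR))).mean()


def dice_loss(pred, target, smooth: float = 1e-5, batched: bool | None = None) -> Tensor:
    """Soft Dice loss on the foreground class, per-item then batch-averaged.

    1 - (2*sum(p*t) + s) / (sum(p) + sum(t) + s), with p the predicted
    foreground probability and t the binary foreground target.
    """
    pred, target = _as_batch(pred, target, batched)
    sp_axes = tuple(range(1, target.ndim))
    dt = pred.data.dtype if np.issubdtype(pred.data.dtype, np.floating) else np.float64
    sel = np.zeros((1, pred.shape[1]) + (1,) * len(sp_axes), dtype=dt)
    sel[0, 1] = 1.0
    fg = (pred * sel).sum(axis=1)          # (N, *sp)
    t = (target == 1).astype(sel.dtype)
    inter = (fg * t).sum(axis=sp_axes)
    denom = fg.sum(axis=sp_axes) + t.sum(axis=sp_axes)
    dice = (2.0 * inter + smooth) / (denom + smooth)
    return (1.0 - dice).mean()


def supervised_loss(pred, target, w: LossWeights = LossWeights(),
                    batched: bool | None = None) -> LossReport:
    """CE + Dice compound loss; also usable for gradient steps via
    :attr:`LossReport.tensors` (``l_ce``/``l_dice``/``l_sup`` tensors)."""
    l_ce = ce_loss(pred, target, batched=batched)
    l_dice = dice_loss(pred, target, smooth=w.dice_smooth, batched=batched)
    l_sup = w.alpha * l_ce + (1.0 - w.alpha) * l_dice
    report = LossReport(l_ce=float(l_ce), l_dice=float(l_dice), l_sup=float(l_sup))
    report.tensors = {"l_ce": l_ce, "l_dice": l_dice, "l_sup": l_sup}
    return report


def unsupervised_loss(pred_3d, pseudo, smooth: float = 1e-5,
                      batched: bool | None = None) -> Tensor:
    """Dice-only consistency loss against frozen pseudo-labels."""
    labels = getattr(pseudo, "labels", pseudo)
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("pseudo-labels must be binary")
    return dice_loss(pred_3d, labels, smooth=smooth, batched=batched)


def total_loss(sup, un) -> float:
    """Unit-weight sum of the supervised and unsupervised terms."""
    s = sup.l_sup if isinstance(sup, LossReport) else float(sup)
    return s + float(un)
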