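"""Two-step training orchestration.

Step 1 trains the 2D attention network on axial slices from labeled
patches with the compound CE+Dice loss.  Its frozen checkpoint then
pseudo-labels every unlabeled patch.  Step 2 trains the 3D network:
each optimization step draws a labeled batch (supervised loss) and an
unlabeled batch scored against its pseudo-labels (Dice-only
consistency loss), summed with unit weights.

Both steps share the optimizer recipe: SGD with momentum 0.9 and a
polynomial learning-rate decay lr = lr0 * (1 - epoch/max_epochs)^0.9
from lr0 = 0.01, early stopping when the validation Dice has not
improved for `patience` epochs, and selection of the checkpoint with
the best validation Dice (never the last epoch).  Augmentation: random
axis flips for both networks, plus cut-out (a zeroed box in the image
only, never the labels) for the 3D network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import evaluation, losses, models, nn, pseudolabel
from .models import forward_2d, forward_3d
from .patching import Patch, crop_patches
from .pseudolabel import PseudoLabelCache
from .volume_io import Cohort, Volume

__all__ = [
    "TrainConfig",
    "TrainState",
    "poly_lr",
    "augment_2d",
    "augment_3d",
    "train_step1",
    "train_step2",
    "run_two_step",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; defaults follow the deployment recipe
    (tests override window/stride/epoch budget with tiny presets)."""

    max_epochs: int = 500
    patience: int = 30
    lr0: float = 0.01
    poly_power: float = 0.9
    momentum: float = 0.9
    weight_decay: float = 0.0
    alpha: float = 0.3
    batch_size_2d: int = 16
    batch_size_3d: int = 4
    steps_per_epoch: int | None = None  # None: one pass over labeled patches
    window: tuple[int, int, int] = (256, 256, 16)
    stride: tuple[int, int, int] = (128, 128, 8)
    flip: bool = True
    cutout: bool = True
    cutout_fraction: float = 0.1  # fraction of patch volume zeroed by cut-out
    val_every: int = 1
    # stride for stitched validation/evaluation inference; None means
    # non-overlapping tiles (stride = window), the cheap default
    eval_stride: tuple[int, int, int] | None = None
    seed: int = 0

    @property
    def eval_stride_or_window(self) -> tuple[int, int, int]:
        return tuple(self.eval_stride) if self.eval_stride else tuple(self.window)

    def __post_init__(self):
        if self.max_epochs < 1 or self.patience < 1 or self.lr0 <= 0:
            raise ValueError("max_epochs >= 1, patience >= 1, lr0 > 0 required")


@dataclass
class TrainState:
    epoch: int = 0
    best_val_dice: float = -np.inf
    best_epoch: int = -1
    epochs_since_improvement: int = 0
    current_lr: float = 0.0
    history: list[dict] = field(default_factory=list)


def poly_lr(epoch: int, cfg: TrainConfig) -> float:
    """Polynomial decay from lr0 at epoch 0 to 0 at max_epochs."""
    if not 0 <= epoch <= cfg.max_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.max_epochs}]")
    return cfg.lr0 * (1.0 - epoch / cfg.max_epochs) ** cfg.poly_power


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------


def augment_2d(image: np.ndarray, labels: np.ndarray, seed) -> tuple[np.ndarray, np.ndarray]:
    """Random flips along both 2D axes, applied jointly to image and labels."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    image = np.asarray(image)
    labels = np.asarray(labels)
    for ax in (0, 1):
        if rng.random() < 0.5:
            image = np.flip(image, axis=ax)
            labels = np.flip(labels, axis=ax)
    return image.copy(), labels.copy()


def cutout_box_shape(patch_shape, fraction: float) -> tuple[int, ...]:
    """Per-axis cut-out box size whose volume is ~`fraction` of the patch."""
    f = fraction ** (1.0 / len(patch_shape))
    return tuple(max(1, int(np.floor(f * n + 0.5))) for n in patch_shape)


def augment_3d(
    patch: np.ndarray,
    labels: np.ndarray,
    seed,
    cutout: bool = True,
    cutout_fraction: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint random axis flips; cut-out zeroes a box in the image only."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    patch = np.asarray(patch)
    labels = np.asarray(labels)
    for ax in (0, 1, 2):
        if rng.random() < 0.5:
            patch = np.flip(patch, axis=ax)
            labels = np.flip(labels, axis=ax)
    patch = patch.copy()
    labels = labels.copy()
    if cutout and cutout_fraction > 0:
        box = cutout_box_shape(patch.shape, cutout_fraction)
        corner = [int(rng.integers(0, n - b + 1)) for n, b in zip(patch.shape, box)]
        sl = tuple(slice(c, c + b) for c, b in zip(corner, box))
        patch[sl] = 0.0
    return patch, labels


# --------------------------------------------------------------------------
# data preparation
# --------------------------------------------------------------------------


def labeled_patch_pairs(cohort: Cohort, cfg: TrainConfig) -> list[tuple[Patch, Patch]]:
    """(image patch, label patch) pairs from all densely labeled volumes."""
    pairs = []
    for v, m in cohort.labeled:
        img_patches = crop_patches(v, cfg.window, cfg.stride)
        lab_patches = crop_patches(m.labels, cfg.window, cfg.stride)
        for ip, lp in zip(img_patches, lab_patches):
            lp.case_id = v.case_id
            ip.case_id = v.case_id
            pairs.append((ip, lp))
    return pairs


def unlabeled_patches(cohort: Cohort, cfg: TrainConfig) -> list[Patch]:
    out = []
    for v in cohort.unlabeled:
        out.extend(crop_patches(v, cfg.window, cfg.stride))
    return out


def _labeled_slices_2d(pairs) -> tuple[np.ndarray, np.ndarray]:
    """All (slice, label-slice) planes from labeled patch pairs."""
    xs, ys = [], []
    for ip, lp in pairs:
        for k in range(ip.data.shape[2]):
            xs.append(ip.data[:, :, k])
            ys.append(lp.data[:, :, k])
    return np.stack(xs), np.stack(ys)


# --------------------------------------------------------------------------
# validation helpers
# --------------------------------------------------------------------------


def validation_dice_2d(model, cohort: Cohort, cfg: TrainConfig) -> float:
    """Mean validation Dice of the 2D network on labeled slices only.

    Each labeled axial slice is windowed with the in-plane window and
    stride, inferred, stitched and argmaxed; metrics use the
    sparse-slice restriction like every other evaluation.
    """
    from .patching import stitch  # local import to avoid cycle noise

    model.eval()
    w2 = (cfg.window[0], cfg.window[1], 1)
    es = cfg.eval_stride_or_window
    s2 = (es[0], es[1], 1)
    dices = []
    for v, m in cohort.validation:
        preds = np.zeros(v.shape, dtype=np.uint8)
        for z in sorted(m.labeled_slices):
            plane = Volume(v.intensities[:, :, z:z + 1], v.spacing, v.case_id)
            patches = crop_patches(plane, w2, s2)
            batch = np.stack([p.data[:, :, 0] for p in patches]).astype(np.float32)
            probs = forward_2d(model, batch).data  # (n, C, wx, wy)
            pairs = [(p.origin, probs[i][:, :, :, None]) for i, p in enumerate(patches)]
            fused = stitch(pairs, plane.shape)
            preds[:, :, z] = np.argmax(fused, axis=0)[:, :, 0]
        met = evaluation.metrics_from_prediction(m, preds)
        dices.append(met["dice"])
    return float(np.mean(dices)) if dices else np.nan


def validation_dice_3d(model, cohort: Cohort, cfg: TrainConfig) -> float:
    model.eval()
    dices = []
    for v, m in cohort.validation:
        met = evaluation.evaluate_case(model, v, m, cfg.window, cfg.eval_stride_or_window)
        dices.append(met["dice"])
    return float(np.mean(dices)) if dices else np.nan


# --------------------------------------------------------------------------
# generic epoch loop with early stopping on validation Dice
# --------------------------------------------------------------------------


def _fit(model, run_epoch, validate, cfg: TrainConfig) -> TrainState:
    """Epoch loop: poly LR, early stopping, best-checkpoint restore."""
    opt = nn.SGD(model.parameters(), lr=cfg.lr0, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
    state = TrainState()
    best_weights = model.state_dict()
    for epoch in range(cfg.max_epochs):
        state.epoch = epoch
        state.current_lr = opt.lr = poly_lr(epoch, cfg)
        model.train()
        losses_this_epoch = run_epoch(epoch, opt)
        val_dice = validate(model) if epoch % cfg.val_every == 0 else None
        improved = val_dice is not None and val_dice > state.best_val_dice
        if improved:
            state.best_val_dice = val_dice
            state.best_epoch = epoch
            state.epochs_since_improvement = 0
            best_weights = model.state_dict()
        else:
            state.epochs_since_improvement += 1
        state.history.append({
            "epoch": epoch,
            "lr": state.current_lr,
            "val_dice": val_dice,
            **losses_this_epoch,
        })
        if state.epochs_since_improvement >= cfg.patience:
            break
    model.load_state_dict(best_weights)
    model.eval()
    return state


# --------------------------------------------------------------------------
# step 1: 2D network on labeled slices
# --------------------------------------------------------------------------


def train_step1(
    cohort: Cohort,
    cfg: TrainConfig,
    net_cfg: models.Net2DConfig = models.TINY_2D,
) -> tuple[models.SwinUNet2D, TrainState]:
    if not cohort.labeled:
        raise ValueError("step 1 requires a non-empty labeled set")
    pairs = labeled_patch_pairs(cohort, cfg)
    xs, ys = _labeled_slices_2d(pairs)
    model = models.build_net2d(net_cfg, seed=cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    w = losses.LossWeights(alpha=cfg.alpha)
    n = len(xs)
    steps = cfg.steps_per_epoch or max(1, n // cfg.batch_size_2d)

    def run_epoch(epoch, opt):
        reports = []
        for _ in range(steps):
            idx = rng.choice(n, size=min(cfg.batch_size_2d, n), replace=False)
            bx, by = [], []
            for i in idx:
                x, y = (augment_2d(xs[i], ys[i], rng) if cfg.flip else (xs[i], ys[i]))
                bx.append(x)
                by.append(y)
            probs = forward_2d(model, np.stack(bx).astype(np.float32))
            rep = losses.supervised_loss(probs, np.stack(by), w, batched=True)
            opt.zero_grad()
            rep.tensors["l_sup"].backward()
            opt.step()
            rep.tensors = None  # free the autodiff graph
            reports.append(rep)
        return {
            "l_ce": float(np.mean([r.l_ce for r in reports])),
            "l_dice": float(np.mean([r.l_dice for r in reports])),
            "l_sup": float(np.mean([r.l_sup for r in reports])),
            "l_un": 0.0,
            "l_total": float(np.mean([r.l_total for r in reports])),
        }

    state = _fit(model, run_epoch, lambda m: validation_dice_2d(m, cohort, cfg), cfg)
    return model, state


# --------------------------------------------------------------------------
# step 2: 3D network with supervised + consistency loss
# --------------------------------------------------------------------------


def train_step2(
    cohort: Cohort,
    pseudo: dict[str, pseudolabel.PseudoLabel] | None,
    cfg: TrainConfig,
    net_cfg: models.Net3DConfig = models.TINY_3D,
    checkpoint_2d: str | None = None,
) -> tuple[models.UNet3D, TrainState]:
    """Train the 3D network; with no unlabeled data this reduces exactly
    to supervised training (no consistency term)."""
    if not cohort.labeled:
        raise ValueError("step 2 requires a non-empty labeled set")
    lab_pairs = labeled_patch_pairs(cohort, cfg)
    unlab = unlabeled_patches(cohort, cfg)
    pseudo = pseudo or {}
    if unlab:
        if checkpoint_2d is None:
            some_key = next(iter(pseudo), None)
            if some_key is None:
                raise KeyError("no pseudo-labels supplied for unlabeled patches")
            checkpoint_2d = some_key.rsplit("|", 1)[1]
        keys = [PseudoLabelCache.key(p.case_id, p.origin, checkpoint_2d) for p in unlab]
        missing = [k for k in keys if k not in pseudo]
        if missing:
            raise KeyError(f"missing pseudo-labels for patches: {missing[:5]}"
                           + (f" (+{len(missing) - 5} more)" if len(missing) > 5 else ""))
        unlab_targets = [pseudo[k].labels for k in keys]

    model = models.build_net3d(net_cfg, seed=cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2,)))
    w = losses.LossWeights(alpha=cfg.alpha)
    n_lab = len(lab_pairs)
    steps = cfg.steps_per_epoch or max(1, n_lab // cfg.batch_size_3d)

    def draw_unlabeled():
        idx = rng.choice(len(unlab), size=min(cfg.batch_size_3d, len(unlab)), replace=False)
        return [(unlab[i].data, unlab_targets[i]) for i in idx]

    def run_epoch(epoch, opt):
        reports = []
        for _ in range(steps):
            idx = rng.choice(n_lab, size=min(cfg.batch_size_3d, n_lab), replace=False)
            bx, by = [], []
            for i in idx:
                ip, lp = lab_pairs[i]
                x, y = ip.data, lp.data
                if cfg.flip or cfg.cutout:
                    x, y = augment_3d(x, y, rng, cutout=cfg.cutout,
                                      cutout_fraction=cfg.cutout_fraction)
                bx.append(x)
                by.append(y)
            probs_l = forward_3d(model, np.stack(bx).astype(np.float32))
            rep = losses.supervised_loss(probs_l, np.stack(by), w, batched=True)
            loss_t = rep.tensors["l_sup"]
            l_un = 0.0
            if unlab:
                ux, uy = [], []
                for x, y in draw_unlabeled():
                    if cfg.flip or cfg.cutout:
                        x, y = augment_3d(x, y, rng, cutout=cfg.cutout,
                                          cutout_fraction=cfg.cutout_fraction)
                    ux.append(x)
                    uy.append(y)
                probs_u = forward_3d(model, np.stack(ux).astype(np.float32))
                l_un_t = losses.unsupervised_loss(probs_u, np.stack(uy),
                                                  smooth=w.dice_smooth, batched=True)
                loss_t = loss_t + l_un_t
                l_un = float(l_un_t)
            opt.zero_grad()
            loss_t.backward()
            opt.step()
            rep.tensors = None  # free the autodiff graph
            rep.l_un = l_un
            rep.l_total = rep.l_sup + l_un
            reports.append(rep)
        return {
            "l_ce": float(np.mean([r.l_ce for r in reports])),
            "l_dice": float(np.mean([r.l_dice for r in reports])),
            "l_sup": float(np.mean([r.l_sup for r in reports])),
            "l_un": float(np.mean([r.l_un for r in reports])),
            "l_total": float(np.mean([r.l_total for r in reports])),
        }

    state = _fit(model, run_epoch, lambda m: validation_dice_3d(m, cohort, cfg), cfg)
    return model, state


# --------------------------------------------------------------------------
# full two-step pipeline
# --------------------------------------------------------------------------


def run_two_step(
    cohort: Cohort,
    cfg: TrainConfig,
    net2d_cfg: models.Net2DConfig = models.TINY_2D,
    net3d_cfg: models.Net3DConfig = models.TINY_3D,
    cache: PseudoLabelCache | None = None,
    step1_cfg: TrainConfig | None = None,
):
    """Train step 1, pseudo-label the unlabeled patches, train step 2.

    Returns (model3d, model2d, pseudo_labels, state1, state2).
    """
    model2d, state1 = train_step1(cohort, step1_cfg or cfg, net2d_cfg)
    unlab = unlabeled_patches(cohort, cfg)
    pseudo = pseudolabel.pseudo_label_cohort(model2d, unlab, cache)
    ckpt = models.checkpoint_id(model2d)
    model3d, state2 = train_step2(cohort, pseudo, cfg, net3d_cfg, checkpoint_2d=ckpt)
    return model3d, model2d, pseudo, state1, state2
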