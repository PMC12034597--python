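"""Learning-rate schedule, augmentation, early stopping and the
orchestration contracts of the two training steps."""

from dataclasses import replace

import numpy as np
import pytest

from mdcl import models, training
from mdcl.training import (
    TrainConfig,
    augment_2d,
    augment_3d,
    cutout_box_shape,
    poly_lr,
    train_step1,
    train_step2,
)

TINY = TrainConfig(max_epochs=3, patience=2, window=(32, 32, 8), stride=(16, 16, 4),
                   steps_per_epoch=2, batch_size_2d=4, batch_size_3d=2, seed=0)


class TestPolyLR:
    def test_initial_value(self):
        assert poly_lr(0, TrainConfig()) == pytest.approx(0.01)

    def test_final_value_zero(self):
        cfg = TrainConfig()
        assert poly_lr(cfg.max_epochs, cfg) == 0.0

    def test_midpoint_closed_form(self):
        cfg = TrainConfig(max_epochs=500, poly_power=0.9)
        assert poly_lr(250, cfg) == pytest.approx(0.01 * 0.5**0.9)

    def test_strictly_decreasing(self):
        cfg = TrainConfig(max_epochs=50)
        vals = [poly_lr(e, cfg) for e in range(51)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_epoch_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            poly_lr(501, TrainConfig(max_epochs=500))


class TestAugment2D:
    def test_double_flip_is_identity(self):
        rng = np.random.default_rng(0)
        img, lab = rng.normal(size=(8, 8)), rng.integers(0, 2, (8, 8))
        once_i = np.flip(img, axis=0)
        np.testing.assert_array_equal(np.flip(once_i, axis=0), img)

    def test_foreground_count_invariant(self):
        rng = np.random.default_rng(1)
        img, lab = rng.normal(size=(8, 8)), (rng.random((8, 8)) < 0.3).astype(int)
        for seed in range(5):
            _, alab = augment_2d(img, lab, seed)
            assert alab.sum() == lab.sum()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        img, lab = rng.normal(size=(8, 8)), rng.integers(0, 2, (8, 8))
        a = augment_2d(img, lab, 7)
        b = augment_2d(img, lab, 7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_image_and_labels_flipped_jointly(self):
        img = np.arange(16.0).reshape(4, 4)
        lab = (img > 7).astype(int)
        for seed in range(8):
            ai, al = augment_2d(img, lab, seed)
            np.testing.assert_array_equal(al, (ai > 7).astype(int))


class TestAugment3D:
    def test_cutout_box_volume_matches_fraction(self):
        box = cutout_box_shape((32, 32, 8), 0.1)
        vol = np.prod(box)
        assert vol == pytest.approx(0.1 * 32 * 32 * 8, rel=0.35)  # integer rounding

    def test_cutout_zeroes_exactly_box_volume(self):
        img = np.ones((16, 16, 8))
        lab = np.zeros((16, 16, 8), int)
        out, _ = augment_3d(img, lab, 3, cutout=True, cutout_fraction=0.1)
        box = cutout_box_shape((16, 16, 8), 0.1)
        assert (out == 0).sum() == np.prod(box)

    def test_labels_never_touched_by_cutout(self):
        rng = np.random.default_rng(4)
        img = rng.normal(size=(16, 16, 8))
        lab = (rng.random((16, 16, 8)) < 0.3).astype(int)
        for seed in range(5):
            _, alab = augment_3d(img, lab, seed, cutout=True, cutout_fraction=0.2)
            assert alab.sum() == lab.sum()

    def test_flip_determinism(self):
        rng = np.random.default_rng(5)
        img = rng.normal(size=(8, 8, 4))
        lab = rng.integers(0, 2, (8, 8, 4))
        a = augment_3d(img, lab, 11)
        b = augment_3d(img, lab, 11)
        np.testing.assert_array_equal(a[0], b[0])


class _FrozenModel(models.UNet3D):
    """3D net whose parameters never update (zero gradients ignored)."""


def _frozen_validate_sequence(values):
    it = iter(values)

    def validate(model):
        return next(it)

    return validate


class TestEarlyStopping:
    def _run_fit(self, val_sequence, patience, max_epochs=20):
        cfg = TrainConfig(max_epochs=max_epochs, patience=patience,
                          window=(32, 32, 8), stride=(16, 16, 4), steps_per_epoch=1)
        model = models.build_net3d(seed=0)

        def run_epoch(epoch, opt):
            return {"l_sup": 0.0, "l_un": 0.0, "l_total": 0.0, "l_ce": 0.0, "l_dice": 0.0}

        state = training._fit(model, run_epoch, _frozen_validate_sequence(val_sequence), cfg)
        return state

    def test_frozen_model_stops_after_patience_epochs(self):
        # improvement only at epoch 0; patience 1 -> stops after epoch 1
        state = self._run_fit([0.5] + [0.5] * 19, patience=1)
        assert state.epoch == 1
        assert state.best_epoch == 0

    def test_stops_exactly_patience_after_last_improvement(self):
        vals = [0.1, 0.2, 0.3] + [0.3] * 17
        state = self._run_fit(vals, patience=3)
        assert state.best_epoch == 2
        assert state.epoch == 5  # 3 non-improving epochs after epoch 2

    def test_never_exceeds_max_epochs(self):
        vals = list(np.linspace(0.1, 0.9, 20))  # always improving
        state = self._run_fit(vals, patience=5, max_epochs=7)
        assert state.epoch == 6
        assert len(state.history) == 7

    def test_best_checkpoint_not_last_is_restored(self):
        cfg = TrainConfig(max_epochs=6, patience=10, window=(32, 32, 8),
                          stride=(16, 16, 4), steps_per_epoch=1)
        model = models.build_net3d(seed=0)
        snapshots = {}

        def run_epoch(epoch, opt):
            # perturb weights every epoch so each epoch has distinct weights
            for p in model.parameters():
                p.data += 0.01
            snapshots[epoch] = model.state_dict()
            return {"l_sup": 0.0, "l_un": 0.0, "l_total": 0.0, "l_ce": 0.0, "l_dice": 0.0}

        state = training._fit(model, run_epoch,
                              _frozen_validate_sequence([0.2, 0.8, 0.3, 0.1, 0.1, 0.1]), cfg)
        assert state.best_epoch == 1
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(v, snapshots[1][k])

    def test_best_dice_nondecreasing_in_history(self):
        state = self._run_fit([0.3, 0.1, 0.4, 0.2, 0.4, 0.4], patience=3)
        best = -np.inf
        for h in state.history:
            if h["val_dice"] is not None:
                best = max(best, h["val_dice"])
        assert best == state.best_val_dice


class TestStepContracts:
    def test_step1_requires_labeled_data(self):
        from mdcl.volume_io import Cohort

        with pytest.raises(ValueError, match="non-empty labeled"):
            train_step1(Cohort([], [], [], []), TINY)

    def test_step2_missing_pseudo_labels_lists_keys(self, tiny_cohort):
        with pytest.raises(KeyError, match="pseudo-label"):
            train_step2(tiny_cohort, {}, TINY)

    def test_step2_without_unlabeled_is_pure_supervised(self, tiny_cohort):
        from mdcl.volume_io import Cohort

        sup = Cohort(tiny_cohort.labeled, [], tiny_cohort.validation, tiny_cohort.test)
        model, state = train_step2(sup, None, TINY)
        assert all(h["l_un"] == 0.0 for h in state.history)
        assert all(h["l_total"] == pytest.approx(h["l_sup"]) for h in state.history)

    def test_step2_loss_log_satisfies_total_identity(self, tiny_cohort):
        model2d, _ = train_step1(tiny_cohort, TINY)
        from mdcl import pseudolabel as pl

        patches = training.unlabeled_patches(tiny_cohort, TINY)
        pseudo = pl.pseudo_label_cohort(model2d, patches)
        model, state = train_step2(tiny_cohort, pseudo, TINY)
        for h in state.history:
            assert h["l_total"] == pytest.approx(h["l_sup"] + h["l_un"], abs=1e-7)
        assert any(h["l_un"] > 0 for h in state.history)

    def test_step1_learns_on_tiny_cohort(self, tiny_cohort):
        """Validation Dice at the selected checkpoint beats epoch 0."""
        cfg = replace(TINY, max_epochs=14, patience=14, steps_per_epoch=8,
                      batch_size_2d=16)
        model, state = train_step1(tiny_cohort, cfg)
        first = state.history[0]["val_dice"]
        assert state.best_val_dice > first

    def test_same_seed_reproduces_loss_history(self, tiny_cohort):
        _, s1 = train_step1(tiny_cohort, TINY)
        _, s2 = train_step1(tiny_cohort, TINY)
        assert [h["l_sup"] for h in s1.history] == [h["l_sup"] for h in s2.history]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(patience=0)
        with pytest.raises(ValueError):
            TrainConfig(lr0=0.0)
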