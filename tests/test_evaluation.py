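"""Segmentation metrics, sparse-slice restriction, seed aggregation and
the signed-rank test against exhaustive enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdcl import evaluation, models
from mdcl.evaluation import (
    aggregate_seeds,
    infer_volume,
    metrics_from_prediction,
    seg_metrics,
    wilcoxon_signed_rank,
)
from mdcl.volume_io import LabelMask, Volume


class TestSegMetrics:
    def test_hand_counted_example(self):
        d, p, r = seg_metrics([0, 1, 1, 0], [0, 1, 0, 0])
        assert d == pytest.approx(2 / 3)
        assert p == pytest.approx(1.0)
        assert r == pytest.approx(0.5)

    def test_identity_prediction_scores_one(self):
        gt = np.array([0, 1, 0, 1, 1])
        assert seg_metrics(gt, gt) == (1.0, 1.0, 1.0)

    def test_complement_prediction_scores_zero_dice(self):
        gt = np.array([0, 1, 0, 1])
        d, p, r = seg_metrics(gt, 1 - gt)
        assert d == 0.0 and p == 0.0 and r == 0.0

    def test_empty_empty_convention(self):
        assert seg_metrics(np.zeros(4, int), np.zeros(4, int)) == (1.0, 1.0, 1.0)

    def test_empty_gt_nonempty_pred(self):
        d, p, r = seg_metrics(np.zeros(4, int), np.array([1, 0, 0, 0]))
        assert d == 0.0 and p == 0.0 and r == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            seg_metrics([0, 1], [0, 1, 1])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 50))
        gt = (rng.random(n) < 0.4).astype(int)
        pred = (rng.random(n) < 0.4).astype(int)
        tp = sum(1 for g, p in zip(gt, pred) if g == 1 and p == 1)
        fp = sum(1 for g, p in zip(gt, pred) if g == 0 and p == 1)
        fn = sum(1 for g, p in zip(gt, pred) if g == 1 and p == 0)
        d, p, r = seg_metrics(gt, pred)
        assert d == pytest.approx(1.0 if 2 * tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn))
        if tp + fp:
            assert p == pytest.approx(tp / (tp + fp))
        if tp + fn:
            assert r == pytest.approx(tp / (tp + fn))
        # algebraic identity: dice is the harmonic mean of precision/recall
        if tp + fp and tp + fn and p + r > 0:
            assert d == pytest.approx(2 * p * r / (p + r))


class TestSparseSliceRule:
    def test_corruption_outside_labeled_slices_is_invisible(self):
        rng = np.random.default_rng(0)
        labels = (rng.random((6, 6, 8)) < 0.3).astype(np.uint8)
        m = LabelMask(labels, frozenset({1, 5}), "sparse")
        pred = (rng.random((6, 6, 8)) < 0.3).astype(np.uint8)
        base = metrics_from_prediction(m, pred)
        corrupted = pred.copy()
        for z in set(range(8)) - {1, 5}:
            corrupted[:, :, z] = 1 - corrupted[:, :, z]
        assert metrics_from_prediction(m, corrupted) == base

    def test_dense_mask_equals_full_volume_metrics(self):
        rng = np.random.default_rng(1)
        labels = (rng.random((5, 5, 5)) < 0.3).astype(np.uint8)
        pred = (rng.random((5, 5, 5)) < 0.3).astype(np.uint8)
        m = LabelMask.dense(labels)
        got = metrics_from_prediction(m, pred)
        d, p, r = seg_metrics(labels.ravel(), pred.ravel())
        assert (got["dice"], got["precision"], got["recall"]) == (d, p, r)

    def test_matches_slice_by_slice_recount(self):
        rng = np.random.default_rng(2)
        labels = (rng.random((4, 4, 6)) < 0.4).astype(np.uint8)
        pred = (rng.random((4, 4, 6)) < 0.4).astype(np.uint8)
        zs = {0, 3}
        m = LabelMask(labels, frozenset(zs), "sparse")
        got = metrics_from_prediction(m, pred)
        gt_cat = np.concatenate([labels[:, :, z].ravel() for z in sorted(zs)])
        pr_cat = np.concatenate([pred[:, :, z].ravel() for z in sorted(zs)])
        d, p, r = seg_metrics(gt_cat, pr_cat)
        assert got == {"dice": d, "precision": p, "recall": r}


class TestInferVolume:
    def test_constant_background_model_gives_empty_segmentation(self):
        model = _constant_model(fg=False)
        v = Volume(np.zeros((48, 48, 12), dtype=np.float32), (1, 1, 1))
        pred = infer_volume(model, v, (32, 32, 8), (16, 16, 4))
        assert pred.sum() == 0

    def test_equals_single_patch_forward_when_volume_fits_window(self):
        model = models.build_net3d(seed=3).eval()
        grid = np.random.default_rng(4).normal(size=(32, 32, 8)).astype(np.float32)
        v = Volume(grid, (1, 1, 1))
        via_pipeline = infer_volume(model, v, (32, 32, 8), (16, 16, 4))
        direct = np.argmax(models.forward_3d(model, grid).data, axis=0)
        np.testing.assert_array_equal(via_pipeline, direct)

    def test_requires_eval_mode(self):
        model = models.build_net3d(seed=0).train()
        v = Volume(np.zeros((32, 32, 8), dtype=np.float32), (1, 1, 1))
        with pytest.raises(RuntimeError, match="evaluation mode"):
            infer_volume(model, v, (32, 32, 8), (16, 16, 4))


def _constant_model(fg: bool):
    """A real 3D net driven to a constant class by its head bias."""
    model = models.build_net3d(seed=0)
    head = model.head
    head.weight.data[:] = 0
    head.bias.data[:] = [-5.0, 5.0] if fg else [5.0, -5.0]
    return model.eval()


class TestAggregateSeeds:
    def test_identical_seeds_reduce_to_single_seed_values(self):
        one = {"a": {"dice": 0.8, "precision": 0.9, "recall": 0.7}}
        rep = aggregate_seeds({0: one, 1: one, 2: one})
        for met, v in one["a"].items():
            assert rep.per_case["a"][met] == pytest.approx(v)
        assert rep.mean["dice"] == pytest.approx(0.8)
        assert rep.sd["dice"] == pytest.approx(0.0)

    def test_hand_computed_two_case_three_seed_table(self):
        per_seed = {
            s: {
                "a": {"dice": da, "precision": 1.0, "recall": 1.0},
                "b": {"dice": db, "precision": 1.0, "recall": 1.0},
            }
            for s, (da, db) in enumerate([(0.6, 0.9), (0.7, 0.8), (0.8, 1.0)])
        }
        rep = aggregate_seeds(per_seed)
        assert rep.per_case["a"]["dice"] == pytest.approx(0.7)
        assert rep.per_case["b"]["dice"] == pytest.approx(0.9)
        assert rep.mean["dice"] == pytest.approx(0.8)
        assert rep.sd["dice"] == pytest.approx(np.std([0.7, 0.9]))
        assert rep.n_cases == 2

    def test_invariant_to_case_ordering(self):
        rng = np.random.default_rng(3)
        cases = {c: {"dice": rng.random(), "precision": 1.0, "recall": 1.0}
                 for c in "abcd"}
        rep1 = aggregate_seeds({0: cases})
        rep2 = aggregate_seeds({0: dict(reversed(list(cases.items())))})
        assert rep1.mean == rep2.mean and rep1.sd == rep2.sd

    def test_mismatched_cases_rejected(self):
        with pytest.raises(ValueError):
            aggregate_seeds({
                0: {"a": {"dice": 1, "precision": 1, "recall": 1}},
                1: {"b": {"dice": 1, "precision": 1, "recall": 1}},
            })


def _exact_wilcoxon_p(diffs):
    """Exhaustive two-sided signed-rank p by enumerating all 2^n sign flips."""
    d = np.asarray(diffs, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    n = len(d)
    mean_w = n * (n + 1) / 4.0
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


class TestWilcoxon:
    def test_identical_samples_degenerate_p_one(self):
        assert wilcoxon_signed_rank([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6]) == 1.0

    def test_n6_matches_exhaustive_enumeration(self):
        a = np.array([0.80, 0.75, 0.90, 0.60, 0.85, 0.70])
        b = np.array([0.72, 0.77, 0.80, 0.55, 0.70, 0.69])
        p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(_exact_wilcoxon_p(a - b), abs=1e-12)

    def test_two_sided_symmetric_under_sign_flip(self):
        a = np.array([0.80, 0.75, 0.90, 0.60, 0.85, 0.70, 0.66])
        b = np.array([0.72, 0.77, 0.80, 0.55, 0.70, 0.69, 0.71])
        assert wilcoxon_signed_rank(a, b) == pytest.approx(wilcoxon_signed_rank(b, a))

    def test_too_few_nonzero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2, 3, 4], [0, 1, 2, 3])

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(5)
        a = rng.normal(1.0, 0.5, size=40)  # clearly shifted sample
        b = np.zeros(40)
        p = wilcoxon_signed_rank(a, b)
        assert 0.0 < p < 0.05
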