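"""Desk-scale paired experiment: two-step consistency training vs the
supervised-only 3D baseline.

The study conditions are a phantom cohort with 2 densely labeled and 6
unlabeled training volumes, 2 sparsely labeled validation volumes and 4
sparsely labeled test volumes of 64x64x32 voxels (noise-free,
high-contrast tubes with confounder blobs), a 32x32x8 sliding window
with 16x16x4 stride, the tiny network presets, and three training
seeds.  Each seed trains the full two-step pipeline and, from the same
cohort stripped of its unlabeled volumes, an identically configured
supervised-only 3D network.  Test metrics follow the sparse-slice rule;
per-case values are averaged over seeds before aggregation.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import evaluation, phantom, training
from .volume_io import Cohort

__all__ = ["EXPERIMENT_SPEC", "experiment_config", "run_comparison"]

# noise-free, high-contrast cohort: the easiest regime the phantom
# generator emulates, where pseudo-labels are expected to be reliable
EXPERIMENT_SPEC = phantom.PhantomSpec(
    grid_size=(64, 64, 32),
    n_tubes=2,
    tube_radius_range=(2.0, 4.0),
    tube_intensity=1.0,
    background_intensity=0.0,
    n_confounders=2,
    noise_sd=0.0,
)


def experiment_config(train_seed: int) -> training.TrainConfig:
    """Desk-scale training configuration (tiny windows, short epoch
    budget with early stopping; see the package methods note)."""
    return training.TrainConfig(
        max_epochs=16,
        patience=6,
        window=(32, 32, 8),
        stride=(16, 16, 4),
        steps_per_epoch=6,
        batch_size_2d=16,
        batch_size_3d=4,
        val_every=2,
        seed=train_seed,
    )


def _strip_unlabeled(cohort: Cohort) -> Cohort:
    return Cohort(cohort.labeled, [], cohort.validation, cohort.test)


def run_comparison(
    master_seed: int,
    n_seeds: int = 3,
    n_labeled: int = 2,
    n_unlabeled: int = 6,
    n_val: int = 2,
    n_test: int = 4,
    step1_epochs: int = 12,
    verbose: bool = False,
) -> dict:
    """Run the paired two-step vs supervised-only comparison.

    Returns a dict with per-seed per-case Dice for both arms, seed-wise
    mean test metrics, the across-seed medians, and a paired Wilcoxon
    signed-rank p-value over (seed, case) Dice pairs when computable.
    """
    cohort = phantom.make_cohort(
        n_labeled, n_unlabeled, n_val, n_test, EXPERIMENT_SPEC, seed=master_seed
    )
    sup_cohort = _strip_unlabeled(cohort)
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(master_seed, spawn_key=(99,)).spawn(n_seeds)]

    per_seed_two_step: dict[int, dict[str, dict[str, float]]] = {}
    per_seed_baseline: dict[int, dict[str, dict[str, float]]] = {}
    for s in seeds:
        cfg = experiment_config(s)
        cfg1 = replace(cfg, max_epochs=step1_epochs, patience=6, val_every=1)
        model3d, _, _, st1, st2 = training.run_two_step(cohort, cfg, step1_cfg=cfg1)
        if verbose:
            print(f"[seed {s}] step1 best val dice {st1.best_val_dice:.3f}, "
                  f"step2 best val dice {st2.best_val_dice:.3f}", flush=True)
        per_seed_two_step[s] = {
            v.case_id: evaluation.evaluate_case(model3d, v, m, cfg.window, cfg.eval_stride_or_window)
            for v, m in cohort.test
        }
        base3d, stb = training.train_step2(sup_cohort, None, cfg)
        if verbose:
            print(f"[seed {s}] baseline best val dice {stb.best_val_dice:.3f}", flush=True)
        per_seed_baseline[s] = {
            v.case_id: evaluation.evaluate_case(base3d, v, m, cfg.window, cfg.eval_stride_or_window)
            for v, m in cohort.test
        }

    agg_two = evaluation.aggregate_seeds(per_seed_two_step)
    agg_base = evaluation.aggregate_seeds(per_seed_baseline)
    seed_means_two = [float(np.mean([c["dice"] for c in per_seed_two_step[s].values()]))
                      for s in seeds]
    seed_means_base = [float(np.mean([c["dice"] for c in per_seed_baseline[s].values()]))
                       for s in seeds]
    pairs_a = [per_seed_two_step[s][c]["dice"] for s in seeds
               for c in sorted(per_seed_two_step[s])]
    pairs_b = [per_seed_baseline[s][c]["dice"] for s in seeds
               for c in sorted(per_seed_baseline[s])]
    try:
        p_value = evaluation.wilcoxon_signed_rank(pairs_a, pairs_b)
    except ValueError:
        p_value = None
    return {
        "seeds": seeds,
        "per_seed_two_step": per_seed_two_step,
        "per_seed_baseline": per_seed_baseline,
        "aggregate_two_step": agg_two,
        "aggregate_baseline": agg_base,
        "median_test_dice_two_step": float(np.median(seed_means_two)),
        "median_test_dice_baseline": float(np.median(seed_means_base)),
        "wilcoxon_p": p_value,
    }
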