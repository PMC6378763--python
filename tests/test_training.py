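"""Splits, training loop behaviour, CV fold structure, grid search."""

import numpy as np
import pandas as pd
import pytest

from ldcnet.network import NetworkSpec
from ldcnet.preprocessing import Patch
from ldcnet.pipeline import CandidateBundle
from ldcnet.training import (
    GridSpec,
    TrainConfig,
    grid_search,
    kfold_cv,
    make_folds,
    make_splits,
    select_best,
    stabilization_epoch,
    train,
)


def toy_patches(n, side, label, value, rng):
    """Bright (nodule-like) or dark patches, linearly separable by intensity."""
    x = np.clip(value + 0.05 * rng.standard_normal((n, side, side)), 0, 1)
    return x.astype(np.float32), np.full(n, label)


class TestMakeSplits:
    def test_exact_60_20_20_on_100(self):
        labels = [0] * 90 + [1] * 10
        assignment = make_splits(labels, seed=0)
        assert assignment.counts() == {"train": 60, "val": 20, "test": 20}

    def test_stratified_by_label(self):
        labels = np.array([0] * 90 + [1] * 10)
        assignment = make_splits(labels, seed=0)
        for split, expected_pos in [("train", 6), ("val", 2), ("test", 2)]:
            idx = assignment.indices(split)
            assert labels[idx].sum() == expected_pos

    def test_deterministic_in_seed(self):
        labels = [0] * 50 + [1] * 10
        a = make_splits(labels, seed=5)
        b = make_splits(labels, seed=5)
        assert (a.assignment == b.assignment).all()
        c = make_splits(labels, seed=6)
        assert not (a.assignment == c.assignment).all()

    def test_within_one_of_ratio_on_awkward_sizes(self):
        for n in (7, 11, 23, 97):
            labels = [0] * n
            counts = make_splits(labels, seed=1).counts()
            assert sum(counts.values()) == n
            assert abs(counts["train"] - 0.6 * n) <= 1
            assert abs(counts["val"] - 0.2 * n) <= 1
            assert abs(counts["test"] - 0.2 * n) <= 1

    def test_too_few_candidates(self):
        with pytest.raises(ValueError, match="at least 5"):
            make_splits([0, 1, 0], seed=0)


class TestTrain:
    def test_learns_linearly_separable_toy_problem(self, tiny_spec, rng):
        bright_x, bright_y = toy_patches(40, 20, 1, 0.8, rng)
        dark_x, dark_y = toy_patches(40, 20, 0, 0.2, rng)
        x = np.concatenate([bright_x, dark_x])
        y = np.concatenate([bright_y, dark_y])
        # small batches give the fixed-lr optimiser enough steps on 80 samples
        config = TrainConfig(epochs=20, batch_size=2, seed=0, loss="focal",
                             gamma=2.0, alpha=0.5)
        model, history = train(tiny_spec, config, x, y)
        from ldcnet.evaluation import confusion, metrics
        from ldcnet.network import predict_proba

        acc = metrics(confusion(predict_proba(model, x), y, 0.5))[0]
        assert acc >= 0.99
        assert len(history) == 20

    def test_history_reproducible_run_to_run(self, tiny_spec, rng):
        x, y = toy_patches(30, 20, 1, 0.6, rng)
        x2, y2 = toy_patches(30, 20, 0, 0.3, rng)
        x, y = np.concatenate([x, x2]), np.concatenate([y, y2])
        config = TrainConfig(epochs=3, batch_size=16, seed=4)
        _, h1 = train(tiny_spec, config, x, y, x[:10], y[:10])
        _, h2 = train(tiny_spec, config, x, y, x[:10], y[:10])
        pd.testing.assert_frame_equal(h1, h2)

    def test_empty_training_set_rejected(self, tiny_spec):
        with pytest.raises(ValueError, match="empty"):
            train(tiny_spec, TrainConfig(epochs=1), np.empty((0, 20, 20)), np.empty(0))

    def test_side_mismatch_rejected(self, tiny_spec, rng):
        x, y = toy_patches(10, 32, 1, 0.5, rng)
        with pytest.raises(ValueError, match="input_side"):
            train(tiny_spec, TrainConfig(epochs=1), x, y)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(loss="hinge")


class TestStabilizationEpoch:
    def test_flat_history_stabilizes_immediately(self):
        h = pd.DataFrame({"epoch": [1, 2, 3], "val_accuracy": [0.9, 0.9, 0.9]})
        assert stabilization_epoch(h) == 1

    def test_step_history(self):
        h = pd.DataFrame({
            "epoch": range(1, 7),
            "val_accuracy": [0.5, 0.6, 0.9, 0.9, 0.9, 0.9],
        })
        assert stabilization_epoch(h) == 3


def make_bundles(n_pos, n_neg, side, rng):
    bundles = []
    for i in range(n_pos + n_neg):
        label = 1 if i < n_pos else 0
        value = 0.8 if label else 0.2
        pixels = np.clip(value + 0.05 * rng.standard_normal((side, side)), 0, 1)
        original = Patch(pixels=pixels.astype(np.float32), label=label)
        variants = []
        if label:
            from ldcnet.augmentation import apply_transform

            variants = [apply_transform(original, t)
                        for t in ("flip_h", "flip_v", "flip_hv")]
        bundles.append(CandidateBundle(
            candidate_index=i, series_id="s", label=label,
            original=original, variants=variants,
        ))
    return bundles


class TestKFoldCV:
    def test_folds_partition_and_balance(self):
        labels = [1] * 7 + [0] * 33
        folds = make_folds(labels, k=5, seed=0)
        sizes = np.bincount(folds, minlength=5)
        assert sizes.sum() == 40
        assert sizes.max() - sizes.min() <= 1
        # positives spread across folds
        pos_per_fold = np.bincount(folds[:7], minlength=5)
        assert pos_per_fold.max() - pos_per_fold.min() <= 1

    def test_k_exceeding_positive_count_rejected(self):
        with pytest.raises(ValueError, match="positives"):
            make_folds([1, 1, 0, 0, 0, 0], k=3, seed=0)

    def test_two_fold_on_toy_set_matches_enumeration(self, tiny_spec, rng):
        bundles = make_bundles(4, 6, 20, rng)
        config = TrainConfig(epochs=2, batch_size=8, seed=0)
        per_fold, aggregate = kfold_cv(bundles, tiny_spec, config, k=2)
        assert len(per_fold) == 2
        # the two test folds partition all 10 candidates
        assert sum(c.total for c in per_fold) == 10
        folds = make_folds([b.label for b in bundles], k=2, seed=config.seed)
        for fold in (0, 1):
            members = [b for b, f in zip(bundles, folds) if f == fold]
            assert per_fold[fold].total == len(members)
        for key in ("accuracy", "sensitivity", "specificity"):
            assert 0 <= aggregate[key] <= 1

    def test_no_augmented_patch_in_any_test_fold(self, tiny_spec, rng):
        bundles = make_bundles(4, 8, 20, rng)
        seen_test_patches = []

        def spy_build(bs, is_train):
            from ldcnet.pipeline import bundles_to_arrays

            if not is_train:
                for b in bs:
                    seen_test_patches.extend(b.patches(include_augmented=False))
                    assert all(not p.is_augmented
                               for p in b.patches(include_augmented=False))
            return bundles_to_arrays(bs, include_augmented=is_train)

        config = TrainConfig(epochs=1, batch_size=8, seed=0)
        kfold_cv(bundles, tiny_spec, config, k=2, build_arrays=spy_build)
        assert len(seen_test_patches) == 12  # originals only, across both folds


class TestGridSearch:
    def fake_evaluator(self, cfg):
        # deterministic pseudo-metrics derived from the configuration
        h = (cfg["gamma"] * 7 + cfg["alpha"] * 13 + cfg["n_blocks"]) % 1.0
        return 0.9 + h / 20, 0.8 + h / 10, 0.85 + h / 15

    def test_budget_one_gives_single_populated_row(self):
        table = grid_search(GridSpec(), 1, self.fake_evaluator, seed=0)
        assert len(table) == 1
        row = table.iloc[0]
        for col in ("accuracy", "sensitivity", "specificity"):
            assert np.isfinite(row[col])

    def test_schema_and_sorting(self):
        table = grid_search(GridSpec(), 8, self.fake_evaluator, seed=1)
        assert list(table.columns) == [
            "input_scale", "batch_size", "n_blocks", "gamma", "alpha",
            "accuracy", "sensitivity", "specificity",
        ]
        acc = table["accuracy"].to_numpy()
        assert (np.diff(acc) <= 1e-12).all()

    def test_draws_stay_inside_grid(self):
        grid = GridSpec()
        table = grid_search(grid, 30, self.fake_evaluator, seed=2)
        assert table["batch_size"].isin(grid.batch_sizes).all()
        assert table["n_blocks"].isin(grid.n_blocks).all()
        assert table["gamma"].isin(grid.gammas).all()
        assert table["alpha"].isin(grid.alphas).all()
        assert table["input_scale"].between(0.3125, 1.0).all()

    def test_selection_prefers_sensitivity_within_accuracy_tolerance(self):
        table = pd.DataFrame([
            {"input_scale": 0.906, "batch_size": 224, "n_blocks": 3,
             "gamma": 2.5, "alpha": 0.5,
             "accuracy": 0.972, "sensitivity": 0.960, "specificity": 0.973},
            {"input_scale": 0.938, "batch_size": 224, "n_blocks": 3,
             "gamma": 1.5, "alpha": 0.5,
             "accuracy": 0.973, "sensitivity": 0.933, "specificity": 0.976},
        ])
        best = select_best(table, sensitivity_priority=True)
        assert best["sensitivity"] == 0.960
        plain = select_best(table, sensitivity_priority=False)
        assert plain["accuracy"] == 0.973

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError):
            grid_search(GridSpec(), 0, self.fake_evaluator)
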