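"""Splitting, training loop, cross-validation and hyperparameter search.

Splitting always happens at the *candidate* level: augmented variants inherit
their source candidate's partition, and validation/test partitions (or
held-out CV folds) only ever see original patches.  This is the leakage guard
that makes the evaluation honest under augmentation.

Training uses Adam (lr 1e-4, beta1 0.9, beta2 0.999, no decay, no early
stopping) for a fixed number of epochs with seeded shuffling, minimising
either the focal loss or plain cross-entropy on the two-class softmax output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evaluation import ConfusionCounts, confusion, metrics
from .focal_loss import FocalParams, batch_loss_and_grad
from .network import LdcNetModel, NetworkSpec, build

__all__ = [
    "TrainConfig",
    "SplitAssignment",
    "GridSpec",
    "make_splits",
    "train",
    "kfold_cv",
    "grid_search",
    "select_best",
    "stabilization_epoch",
]

SPLIT_NAMES = ("train", "val", "test")


@dataclass
class TrainConfig:
    """Optimiser and loss settings (Adam with fixed hyperparameters)."""

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 100
    batch_size: int = 224
    seed: int = 0
    loss: str = "focal"  # or "cross_entropy"
    gamma: float = 2.5
    alpha: float = 0.5
    input_scale: float = 1.0
    n_blocks: int = 3

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss not in ("focal", "cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")

    @property
    def focal_params(self) -> FocalParams:
        return FocalParams(gamma=self.gamma, alpha=self.alpha)


@dataclass
class SplitAssignment:
    """Per-candidate partition labels; augmented variants follow their source."""

    assignment: np.ndarray  # array of "train"/"val"/"test", one per candidate

    def indices(self, split: str) -> np.ndarray:
        if split not in SPLIT_NAMES:
            raise ValueError(f"unknown split {split!r}")
        return np.flatnonzero(self.assignment == split)

    def counts(self) -> dict[str, int]:
        return {s: int(np.sum(self.assignment == s)) for s in SPLIT_NAMES}


def make_splits(
    labels, ratios: tuple[float, float, float] = (0.6, 0.2, 0.2), seed: int = 0
) -> SplitAssignment:
    """Stratified 60/20/20 candidate split, deterministic in *seed*.

    ``labels`` is the per-candidate 0/1 label sequence; each class is shuffled
    and cut at the cumulative ratios, so every split holds its share of the
    rare positives.
    """
    labels = np.asarray(labels)
    if len(labels) < 5:
        raise ValueError("need at least 5 candidates to split")
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=object)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(np.floor(n * ratios[0] + 0.5))
        n_val = int(np.floor(n * (ratios[0] + ratios[1]) + 0.5)) - n_train
        assignment[idx[:n_train]] = "train"
        assignment[idx[n_train : n_train + n_val]] = "val"
        assignment[idx[n_train + n_val :]] = "test"
    return SplitAssignment(assignment=assignment.astype(str))


def train(
    spec: NetworkSpec,
    config: TrainConfig,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray | None = None,
    val_y: np.ndarray | None = None,
) -> tuple[LdcNetModel, pd.DataFrame]:
    """Train an LdcNet; returns the model and a per-epoch history frame.

    History columns: epoch (1-based), train_loss (mean over batches) and
    val_accuracy (NaN when no validation data is given).  Fully deterministic
    given (seed, data, config).
    """
    train_x = np.asarray(train_x, dtype=np.float32)
    train_y = np.asarray(train_y)
    if len(train_x) == 0:
        raise ValueError("empty training set")
    if train_x.shape[1] != spec.input_side:
        raise ValueError(
            f"training patches side {train_x.shape[1]} != spec input_side "
            f"{spec.input_side}"
        )
    model = build(spec, seed=config.seed)
    optimizer = model.make_optimizer(
        lr=config.learning_rate, beta1=config.beta1, beta2=config.beta2
    )
    rng = np.random.default_rng([config.seed, 0x5EED])
    params = config.focal_params
    rows = []
    n = len(train_x)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            p = model.forward(train_x[batch], train=True, rng=rng)
            loss, grad = batch_loss_and_grad(
                p, train_y[batch], params, kind=config.loss
            )
            model.backward(grad)
            optimizer.step()
            losses.append((loss, len(batch)))
        total = sum(k for _, k in losses)
        train_loss = sum(l * k for l, k in losses) / total
        if val_x is not None and len(val_x):
            from .network import predict_proba

            scores = predict_proba(model, val_x)
            val_acc = metrics(confusion(scores, val_y, 0.5))[0]
        else:
            val_acc = float("nan")
        rows.append({"epoch": epoch, "train_loss": train_loss, "val_accuracy": val_acc})
    return model, pd.DataFrame(rows)


def stabilization_epoch(history: pd.DataFrame, tol: float = 0.02) -> int:
    """First epoch after which validation accuracy never drops below its
    final value minus *tol* — when the curve enters its plateau band for
    good.  One-sided: exceeding the final value never resets stabilisation,
    only dips below the band do; *tol* absorbs the counting noise of a
    finite validation set."""
    acc = history["val_accuracy"].to_numpy()
    stable = acc >= acc[-1] - tol
    for e in range(len(acc)):
        if stable[e:].all():
            return int(history["epoch"].iloc[e])
    return int(history["epoch"].iloc[-1])


def make_folds(labels, k: int, seed: int = 0) -> np.ndarray:
    """Assign each candidate to one of *k* folds (sizes differ by <= 1),
    spreading the positives evenly; deterministic in *seed*."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    n_pos = int(np.sum(labels == 1))
    if k > n_pos:
        raise ValueError(f"k={k} exceeds the number of positives ({n_pos})")
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels != 1)
    rng.shuffle(pos)
    rng.shuffle(neg)
    order = np.concatenate([pos, neg])
    folds = np.empty(len(labels), dtype=int)
    folds[order] = np.arange(len(labels)) % k
    return folds


def kfold_cv(
    bundles,
    spec: NetworkSpec,
    config: TrainConfig,
    k: int = 10,
    build_arrays=None,
) -> tuple[list[ConfusionCounts], dict]:
    """k-fold cross-validation over candidate bundles.

    Each iteration trains on the other k-1 folds (originals plus augmented
    variants) and evaluates on the *original* patches of the held-out fold at
    threshold 0.5.  ``build_arrays(bundles, train=bool)`` converts bundles to
    (X, y); the default uses each bundle's patches at the spec input side.
    Returns per-fold confusion counts and aggregate metrics over their sum.
    """
    from .pipeline import bundles_to_arrays  # default array builder

    if build_arrays is None:
        def build_arrays(bs, train):
            return bundles_to_arrays(bs, include_augmented=train)

    labels = [b.label for b in bundles]
    folds = make_folds(labels, k, seed=config.seed)
    per_fold: list[ConfusionCounts] = []
    for fold in range(k):
        train_b = [b for b, f in zip(bundles, folds) if f != fold]
        test_b = [b for b, f in zip(bundles, folds) if f == fold]
        tx, ty = build_arrays(train_b, True)
        ex, ey = build_arrays(test_b, False)
        fold_config = replace(config, seed=config.seed + fold)
        model, _ = train(spec, fold_config, tx, ty)
        from .network import predict_proba

        scores = predict_proba(model, ex)
        per_fold.append(confusion(scores, ey, 0.5))
    aggregate = sum(per_fold[1:], per_fold[0])
    acc, sens, spec_ = metrics(aggregate)
    return per_fold, {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec_,
        "confusion": aggregate,
    }


@dataclass
class GridSpec:
    """The hyperparameter search space.

    The alpha axis is restricted to [0.2, 1.0]: the class weight is a
    probability-style factor (the negative-class weight is 1 - alpha), so
    values above 1 would weight negatives negatively.
    """

    input_scale: tuple[float, float] = (0.3125, 1.0)
    batch_sizes: tuple[int, ...] = (128, 160, 192, 224, 256)
    n_blocks: tuple[int, ...] = (2, 3, 4)
    gammas: tuple[float, ...] = tuple(np.round(np.arange(0.5, 5.01, 0.5), 2))
    alphas: tuple[float, ...] = tuple(np.round(np.arange(0.2, 1.001, 0.1), 2))


def grid_search(
    grid: GridSpec,
    budget: int,
    evaluate_fn,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate *budget* random draws from the grid and tabulate the results.

    ``evaluate_fn(config_dict)`` receives keys input_scale, batch_size,
    n_blocks, gamma, alpha and returns (accuracy, sensitivity, specificity)
    as fractions.  Rows come back sorted best-first by accuracy, ties broken
    by sensitivity.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(budget):
        cfg = {
            "input_scale": float(np.round(rng.uniform(*grid.input_scale), 3)),
            "batch_size": int(rng.choice(grid.batch_sizes)),
            "n_blocks": int(rng.choice(grid.n_blocks)),
            "gamma": float(rng.choice(grid.gammas)),
            "alpha": float(rng.choice(grid.alphas)),
        }
        acc, sens, spec_ = evaluate_fn(cfg)
        rows.append({**cfg, "accuracy": acc, "sensitivity": sens, "specificity": spec_})
    df = pd.DataFrame(
        rows,
        columns=[
            "input_scale", "batch_size", "n_blocks", "gamma", "alpha",
            "accuracy", "sensitivity", "specificity",
        ],
    )
    return df.sort_values(
        ["accuracy", "sensitivity"], ascending=False, kind="stable"
    ).reset_index(drop=True)


def select_best(
    table: pd.DataFrame,
    sensitivity_priority: bool = True,
    accuracy_tolerance: float = 0.005,
) -> pd.Series:
    """Pick the winning configuration from a grid-search table.

    With sensitivity priority (the default), any row whose accuracy is within
    ``accuracy_tolerance`` of the best accuracy competes, and the most
    sensitive of them wins — so a (0.972, 0.960) row beats a (0.973, 0.933)
    one.  Without it, plain accuracy-then-sensitivity ordering decides.
    """
    if table.empty:
        raise ValueError("empty results table")
    if not sensitivity_priority:
        ordered = table.sort_values(
            ["accuracy", "sensitivity"], ascending=False, kind="stable"
        )
        return ordered.iloc[0]
    best_acc = table["accuracy"].max()
    pool = table[table["accuracy"] >= best_acc - accuracy_tolerance]
    pool = pool.sort_values(
        ["sensitivity", "accuracy"], ascending=False, kind="stable"
    )
    return pool.iloc[0]
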