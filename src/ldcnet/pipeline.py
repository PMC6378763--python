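"""End-to-end wiring: dataset -> patches -> splits -> training -> metrics.

A :class:`CandidateBundle` holds everything the trainer needs for one
candidate: its original patch and (for positives) the augmented variants.
Bundles are the unit of splitting and cross-validation, which is what keeps
augmented copies from leaking across partition boundaries.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .augmentation import augment_candidate
from .evaluation import auc as roc_auc
from .evaluation import confusion, metrics, roc
from .image_io import Candidate, CTVolume, read_candidates_csv, read_metaimage, world_to_voxel
from .network import NetworkSpec, default_spec, predict_proba
from .preprocessing import (
    PATCH_SIDE,
    Patch,
    hu_normalize,
    rescale_patch,
    extract_patch,
)
from .training import (
    SplitAssignment,
    TrainConfig,
    make_splits,
    stabilization_epoch,
    train,
)

__all__ = [
    "CandidateBundle",
    "LeakageError",
    "load_dataset",
    "extract_bundles",
    "bundles_to_arrays",
    "split_arrays",
    "assert_no_leakage",
    "run_phantom_experiment",
]


class LeakageError(AssertionError):
    """An augmented variant escaped its source candidate's partition."""


@dataclass
class CandidateBundle:
    """One candidate's patches: the original plus any augmented variants."""

    candidate_index: int
    series_id: str
    label: int
    original: Patch
    variants: list[Patch] = field(default_factory=list)

    def patches(self, include_augmented: bool) -> list[Patch]:
        return [self.original] + (self.variants if include_augmented else [])


@dataclass
class Dataset:
    """A LUNA16-layout directory held as paths; volumes load on demand."""

    root: str
    candidates: list[Candidate]

    def volume(self, series_id: str) -> CTVolume:
        return read_metaimage(os.path.join(self.root, f"{series_id}.mhd"))


def load_dataset(root: str | os.PathLike) -> Dataset:
    root = os.fspath(root)
    return Dataset(
        root=root,
        candidates=read_candidates_csv(os.path.join(root, "candidates.csv")),
    )


def extract_bundles(
    dataset: Dataset,
    augment_positives: bool = True,
    side: int = PATCH_SIDE,
) -> tuple[list[CandidateBundle], int]:
    """Extract one bundle per candidate, slice by slice.

    Candidates rejected by the edge rule are dropped; the second return value
    counts them.  Positive candidates get their augmentation variants here
    (negatives are never augmented).
    """
    bundles: list[CandidateBundle] = []
    n_rejected = 0
    by_series: dict[str, list[tuple[int, Candidate]]] = {}
    for i, cand in enumerate(dataset.candidates):
        by_series.setdefault(cand.series_id, []).append((i, cand))
    for series_id, members in by_series.items():
        volume = dataset.volume(series_id)
        norm_slices: dict[int, np.ndarray] = {}
        for index, cand in members:
            z, r, c = world_to_voxel(volume, cand.center)
            nz = volume.voxels.shape[0]
            if not 0 <= z < nz:
                n_rejected += 1
                continue
            if z not in norm_slices:
                norm_slices[z] = hu_normalize(volume.voxels[z])
            slice2d = norm_slices[z]
            if cand.label == 1 and augment_positives:
                try:
                    patches = augment_candidate(
                        slice2d, (r, c),
                        label=1, series_id=series_id, slice_index=z,
                    )
                except ValueError:
                    n_rejected += 1
                    continue
                original, variants = patches[0], patches[1:]
            else:
                original = extract_patch(
                    slice2d, (r, c), side,
                    label=cand.label, series_id=series_id, slice_index=z,
                )
                if original is None:
                    n_rejected += 1
                    continue
                variants = []
            bundles.append(
                CandidateBundle(
                    candidate_index=index,
                    series_id=series_id,
                    label=cand.label,
                    original=original,
                    variants=variants,
                )
            )
    return bundles, n_rejected


def bundles_to_arrays(
    bundles: list[CandidateBundle],
    include_augmented: bool,
    scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack bundle patches into (X, y); rescales when scale != 1."""
    xs, ys = [], []
    for b in bundles:
        for p in b.patches(include_augmented):
            if scale != 1.0:
                p = rescale_patch(p, scale)
            xs.append(p.pixels)
            ys.append(p.label)
    if not xs:
        return np.empty((0,)), np.empty((0,))
    return np.stack(xs).astype(np.float32), np.asarray(ys)


def split_arrays(
    bundles: list[CandidateBundle],
    assignment: SplitAssignment,
    scale: float = 1.0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Materialise train/val/test arrays from bundles under an assignment.

    Train receives originals plus augmented variants; val and test receive
    originals only.  Raises :class:`LeakageError` if any bundle's patches
    would land outside its candidate's partition (checked by construction,
    asserted anyway)."""
    assert_no_leakage(bundles, assignment)
    out = {}
    for split in ("train", "val", "test"):
        idx = set(assignment.indices(split).tolist())
        members = [b for b in bundles if b.candidate_index in idx]
        out[split] = bundles_to_arrays(
            members, include_augmented=(split == "train"), scale=scale
        )
    return out


def assert_no_leakage(
    bundles: list[CandidateBundle], assignment: SplitAssignment
) -> None:
    """Check the structural preconditions that make the split leak-free:
    the assignment is per-candidate (so every patch of a bundle shares one
    partition by construction), every stored variant is marked augmented
    (so the originals-only rule for val/test is enforceable), and the
    original patch is never an augmented one."""
    splits = assignment.assignment
    if not set(np.unique(splits)) <= {"train", "val", "test"}:
        raise LeakageError(f"unknown split names in assignment: {np.unique(splits)}")
    for b in bundles:
        if not 0 <= b.candidate_index < len(splits):
            raise LeakageError(
                f"bundle candidate_index {b.candidate_index} outside assignment"
            )
        if b.original.is_augmented:
            raise LeakageError("original patch is marked augmented")
        for p in b.variants:
            if not p.is_augmented:
                raise LeakageError("non-augmented patch stored as variant")


def run_phantom_experiment(
    seed: int,
    *,
    n_scans: int = 4,
    candidates_per_scan: int = 250,
    positive_fraction: float = 1.0 / 51.0,
    loss: str = "focal",
    gamma: float = 2.5,
    alpha: float = 0.5,
    epochs: int = 10,
    input_scale: float = 0.5,
    batch_size: int = 32,
    workdir: str | None = None,
    spec: NetworkSpec | None = None,
) -> dict:
    """The full pipeline on phantom data: synth -> extract -> augment ->
    train -> eval.  Returns test metrics, the ROC AUC and the history.

    The phantom, the split and the network seed all derive from *seed*, so a
    rerun reproduces the result exactly.
    """
    import tempfile

    from .synthetic_data import PhantomConfig, generate_dataset

    config = PhantomConfig(
        n_scans=n_scans,
        candidates_per_scan=candidates_per_scan,
        positive_fraction=positive_fraction,
        seed=seed,
    )
    own_tmp = workdir is None
    tmp_ctx = tempfile.TemporaryDirectory() if own_tmp else None
    data_dir = tmp_ctx.name if own_tmp else workdir
    try:
        generate_dataset(config, data_dir)
        dataset = load_dataset(data_dir)
        bundles, n_rejected = extract_bundles(dataset, augment_positives=True)
        assignment = make_splits([b.label for b in bundles], seed=seed)
        # reindex bundles against the assignment (bundle order = label order)
        for position, b in enumerate(bundles):
            b.candidate_index = position
        arrays = split_arrays(bundles, assignment, scale=input_scale)
        (tx, ty), (vx, vy), (ex, ey) = arrays["train"], arrays["val"], arrays["test"]
        side = tx.shape[1]
        net_spec = spec if spec is not None else default_spec(input_side=side)
        if net_spec.input_side != side:
            raise ValueError("spec input_side does not match scaled patch side")
        tcfg = TrainConfig(
            epochs=epochs,
            batch_size=batch_size,
            seed=seed,
            loss=loss,
            gamma=gamma,
            alpha=alpha,
            input_scale=input_scale,
        )
        model, history = train(net_spec, tcfg, tx, ty, vx, vy)
        scores = predict_proba(model, ex)
        counts = confusion(scores, ey, 0.5)
        accuracy, sensitivity, specificity = metrics(counts)
        curve = roc(scores, ey)
        return {
            "accuracy": accuracy,
            "sensitivity": sensitivity,
            "specificity": specificity,
            "auc": roc_auc(curve),
            "confusion": counts,
            "history": history,
            "stabilization_epoch": stabilization_epoch(history),
            "n_candidates": len(dataset.candidates),
            "n_bundles": len(bundles),
            "n_rejected": n_rejected,
            "n_train_patches": len(tx),
            "n_test": len(ex),
            "n_test_positive": int(np.sum(ey == 1)),
            "model": model,
            "scores": scores,
            "test_labels": ey,
        }
    finally:
        if tmp_ctx is not None:
            tmp_ctx.cleanup()
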