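"""HU normalisation, patch extraction and patch rescaling.

Candidate locations are turned into fixed-size 2D tiles taken from the single
axial slice that contains the candidate voxel.  Intensities are windowed to
the [-1000, 400] HU range relevant for lung parenchyma and soft tissue and
mapped linearly to [0, 1].  Candidates closer than half a patch side to a
slice edge are rejected rather than padded.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage.transform import resize

HU_MIN = -1000.0
HU_MAX = 400.0
PATCH_SIDE = 64
MIN_SCALE = 0.3125  # 64 * 0.3125 = 20 px, the smallest input the network accepts
MAX_SCALE = 1.0

#: closed vocabulary of patch provenance tags
TRANSFORM_TAGS = (
    ("orig",)
    + tuple(f"rot{s:+d}" for s in range(-25, 30, 5) if s != 0)
    + ("flip_h", "flip_v", "flip_hv")
)

__all__ = [
    "Patch",
    "hu_normalize",
    "hu_denormalize",
    "extract_patch",
    "rescale_patch",
    "save_patch_archive",
    "load_patch_archive",
    "TRANSFORM_TAGS",
    "PATCH_SIDE",
    "HU_MIN",
    "HU_MAX",
    "MIN_SCALE",
    "MAX_SCALE",
]


@dataclass
class Patch:
    """A normalized square intensity tile with its label and provenance."""

    pixels: np.ndarray
    label: int
    series_id: str = ""
    center_voxel: tuple[int, int, int] = (0, 0, 0)  # (slice, row, col)
    is_augmented: bool = False
    transform_tag: str = "orig"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("pixels must be a square 2D array")
        if self.side < 20:
            raise ValueError(f"patch side must be >= 20, got {self.side}")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.transform_tag not in TRANSFORM_TAGS:
            raise ValueError(f"unknown transform_tag {self.transform_tag!r}")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(f"pixels must lie in [0,1], got range [{lo}, {hi}]")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def hu_normalize(hu: np.ndarray) -> np.ndarray:
    """Window HU values to [-1000, 400] and map linearly onto [0, 1].

    I_norm = (clip(I_HU, -1000, 400) + 1000) / 1400.  Monotone non-decreasing
    in the input; air maps to 0, bone saturates at 1.
    """
    hu = np.asarray(hu, dtype=np.float32)
    if np.isnan(hu).any():
        raise ValueError("HU array contains NaN")
    return (np.clip(hu, HU_MIN, HU_MAX) - HU_MIN) / (HU_MAX - HU_MIN)


def hu_denormalize(norm: np.ndarray) -> np.ndarray:
    """Inverse affine map of :func:`hu_normalize` (exact on non-clipped values)."""
    return np.asarray(norm, dtype=np.float32) * (HU_MAX - HU_MIN) + HU_MIN


def patch_center_accepted(
    shape: tuple[int, int], center: tuple[int, int], side: int = PATCH_SIDE
) -> bool:
    """True when a side x side window around *center* fits inside the slice.

    The acceptance region is ``side/2 <= c <= dim - side/2`` per axis; the
    window itself is the half-open square ``[c - side/2, c + side/2)``.
    """
    half = side // 2
    r, c = center
    rows, cols = shape
    return half <= r <= rows - half and half <= c <= cols - half


def extract_patch(
    slice2d: np.ndarray,
    center: tuple[int, int],
    side: int = PATCH_SIDE,
    *,
    label: int = 0,
    series_id: str = "",
    slice_index: int = 0,
) -> Patch | None:
    """Cut a side x side normalized patch around *center*, or return ``None``
    when the candidate lies within ``side/2`` pixels of a slice edge."""
    slice2d = np.asarray(slice2d)
    if side % 2:
        raise ValueError(f"side must be even, got {side}")
    if side > min(slice2d.shape):
        raise ValueError(f"side {side} exceeds slice dims {slice2d.shape}")
    if not patch_center_accepted(slice2d.shape, center, side):
        return None
    half = side // 2
    r, c = center
    window = slice2d[r - half : r + half, c - half : c + half]
    return Patch(
        pixels=window,
        label=label,
        series_id=series_id,
        center_voxel=(slice_index, int(r), int(c)),
        is_augmented=False,
        transform_tag="orig",
    )


def rescale_patch(p: Patch, scale: float) -> Patch:
    """Resample a 64 px patch to side ``round(64 * scale)`` (bilinear).

    The network's input-scale hyperparameter: scale 0.3125 gives the 20 px
    minimum, 1.0 is the identity.  Output intensities are clamped to [0, 1].
    """
    if not MIN_SCALE <= scale <= MAX_SCALE:
        raise ValueError(f"scale must be in [{MIN_SCALE}, {MAX_SCALE}], got {scale}")
    if p.side != PATCH_SIDE:
        raise ValueError(f"rescale_patch expects a {PATCH_SIDE} px patch, got {p.side}")
    if scale == 1.0:
        return p
    new_side = int(np.floor(PATCH_SIDE * scale + 0.5))
    pixels = resize(
        p.pixels, (new_side, new_side), order=1, anti_aliasing=False, mode="edge"
    )
    return replace(p, pixels=np.clip(pixels, 0.0, 1.0).astype(np.float32))


# ---------------------------------------------------------------------------
# Patch archives: a directory holding one .npy stack plus a manifest CSV.

_MANIFEST_COLS = [
    "index",
    "series_id",
    "center_slice",
    "center_row",
    "center_col",
    "label",
    "is_augmented",
    "transform_tag",
]


def save_patch_archive(patches: list[Patch], out_dir: str | os.PathLike) -> None:
    """Write patches as ``patches.npy`` plus ``manifest.csv`` under *out_dir*."""
    if not patches:
        raise ValueError("no patches to save")
    sides = {p.side for p in patches}
    if len(sides) > 1:
        raise ValueError(f"mixed patch sides {sorted(sides)} in one archive")
    os.makedirs(out_dir, exist_ok=True)
    stack = np.stack([p.pixels for p in patches]).astype(np.float32)
    np.save(os.path.join(out_dir, "patches.npy"), stack)
    rows = [
        {
            "index": i,
            "series_id": p.series_id,
            "center_slice": p.center_voxel[0],
            "center_row": p.center_voxel[1],
            "center_col": p.center_voxel[2],
            "label": p.label,
            "is_augmented": int(p.is_augmented),
            "transform_tag": p.transform_tag,
        }
        for i, p in enumerate(patches)
    ]
    pd.DataFrame(rows, columns=_MANIFEST_COLS).to_csv(
        os.path.join(out_dir, "manifest.csv"), index=False
    )
    with open(os.path.join(out_dir, "archive.json"), "w") as fh:
        json.dump({"n_patches": len(patches), "side": patches[0].side}, fh)


def load_patch_archive(in_dir: str | os.PathLike) -> list[Patch]:
    stack = np.load(os.path.join(in_dir, "patches.npy"))
    manifest = pd.read_csv(os.path.join(in_dir, "manifest.csv"))
    if len(stack) != len(manifest):
        raise ValueError("patch stack and manifest disagree on length")
    patches = []
    for _, row in manifest.iterrows():
        patches.append(
            Patch(
                pixels=stack[int(row["index"])],
                label=int(row["label"]),
                series_id=str(row["series_id"]),
                center_voxel=(
                    int(row["center_slice"]),
                    int(row["center_row"]),
                    int(row["center_col"]),
                ),
                is_augmented=bool(row["is_augmented"]),
                transform_tag=str(row["transform_tag"]),
            )
        )
    return patches
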