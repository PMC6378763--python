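"""Positive-patch augmentation: small rotations and axis flips.

Nodules are augmented with rotations from -25 to +25 degrees in 5-degree
steps (0 excluded — it would duplicate the original) plus the three axis
flips, giving at most 1 + 10 + 3 = 14 variants per candidate.  Nonuniform
transforms (stretch/skew) are deliberately absent: nodule shape is the
discriminative signal.  Rotations are computed on a 91 px context window
(91 = ceil(64 * sqrt(2)), large enough that the rotated 64 px crop never
samples outside the window) and are discarded for candidates whose context
window would leave the slice.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage

from .preprocessing import PATCH_SIDE, TRANSFORM_TAGS, Patch, extract_patch

#: side of the rotation support window: ceil(64 * sqrt(2))
CONTEXT_SIDE = 91
#: minimum distance of a candidate centre from every slice edge for rotations
ROTATION_MARGIN = 46  # ceil(91 / 2)

ROTATION_TAGS = tuple(t for t in TRANSFORM_TAGS if t.startswith("rot"))
FLIP_TAGS = ("flip_h", "flip_v", "flip_hv")

__all__ = [
    "apply_transform",
    "augment_candidate",
    "rotation_allowed",
    "CONTEXT_SIDE",
    "ROTATION_MARGIN",
    "ROTATION_TAGS",
    "FLIP_TAGS",
]


def _tag_angle(tag: str) -> int:
    return int(tag[3:])


def _rotate(pixels: np.ndarray, angle_deg: float) -> np.ndarray:
    out = ndimage.rotate(
        pixels, angle_deg, reshape=False, order=1, mode="nearest", prefilter=False
    )
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _flip(pixels: np.ndarray, tag: str) -> np.ndarray:
    if tag == "flip_h":
        return pixels[:, ::-1].copy()
    if tag == "flip_v":
        return pixels[::-1, :].copy()
    return pixels[::-1, ::-1].copy()  # flip_hv


def apply_transform(p: Patch, tag: str) -> Patch:
    """Apply one vocabulary transform to a patch, recording its provenance.

    Flips are exact pixel permutations (involutions); rotations resample the
    patch in place with bilinear interpolation, so ``rot+a`` then ``rot-a``
    reproduces the original only up to interpolation error.
    """
    if tag not in TRANSFORM_TAGS:
        raise ValueError(f"unknown transform tag {tag!r}")
    if tag == "orig":
        return replace(p, pixels=p.pixels.copy())
    if tag in FLIP_TAGS:
        pixels = _flip(p.pixels, tag)
    else:
        pixels = _rotate(p.pixels, _tag_angle(tag))
    return replace(p, pixels=pixels, is_augmented=True, transform_tag=tag)


def rotation_allowed(shape: tuple[int, int], center: tuple[int, int]) -> bool:
    """True when the 91 px rotation context window fits inside the slice."""
    r, c = center
    rows, cols = shape
    return (
        ROTATION_MARGIN <= r <= rows - ROTATION_MARGIN
        and ROTATION_MARGIN <= c <= cols - ROTATION_MARGIN
    )


def augment_candidate(
    slice2d: np.ndarray,
    center: tuple[int, int],
    *,
    label: int = 1,
    series_id: str = "",
    slice_index: int = 0,
) -> list[Patch]:
    """Produce the original patch plus its surviving augmented variants.

    Always yields the original and the three flips (4 patches).  The ten
    rotated variants are produced from a context window centred on the
    candidate and cropped back to 64 px; they are discarded wholesale when the
    candidate sits closer than 46 px to any slice edge.  Maximum yield: 14.
    """
    slice2d = np.asarray(slice2d)
    original = extract_patch(
        slice2d, center, PATCH_SIDE,
        label=label, series_id=series_id, slice_index=slice_index,
    )
    if original is None:
        raise ValueError(f"candidate centre {center} is rejected by extract_patch")

    out = [original]
    if rotation_allowed(slice2d.shape, center):
        r, c = center
        half = CONTEXT_SIDE // 2  # 45; window rows r-45 .. r+45 inclusive
        context = slice2d[r - half : r + half + 1, c - half : c + half + 1]
        crop0 = half - PATCH_SIDE // 2  # 13
        for tag in ROTATION_TAGS:
            rotated = _rotate(context, _tag_angle(tag))
            pixels = rotated[crop0 : crop0 + PATCH_SIDE, crop0 : crop0 + PATCH_SIDE]
            out.append(
                replace(original, pixels=pixels, is_augmented=True, transform_tag=tag)
            )
    for tag in FLIP_TAGS:
        out.append(apply_transform(original, tag))
    return out
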