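"""Seeded CT phantom generator in the LUNA16 layout.

Each phantom scan is an elliptical "lung" of noisy parenchyma (about -850 HU)
inside an air background, wrapped in a soft-tissue chest-wall rim.  Positive
candidates are soft-tissue ellipsoidal nodules (3-30 mm, near-spherical, with
smoothly blurred margins); negative candidates sit on vessel-like distractors
(elongated bright cylinders at soft-tissue HU) and on points along the
lung/chest-wall boundary, mimicking the vessels and rib edges that dominate
real screening false positives.  Class imbalance defaults to 1:50.  Every
nodule is annotated independently by each simulated reader with a detection
probability and sub-voxel jitter, so annotation merging and consensus
filtering can be exercised end to end.  Generation is a pure function of
(seed, scan_index).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import (
    Candidate,
    CTVolume,
    NoduleAnnotation,
    WorldPoint,
    voxel_to_world,
    write_annotations_csv,
    write_candidates_csv,
    write_metaimage,
)

__all__ = ["PhantomConfig", "generate_scan", "generate_dataset", "GenerationError"]


class GenerationError(RuntimeError):
    """Raised when object placement fails after bounded retries."""


@dataclass
class PhantomConfig:
    """Study conditions for the phantom.

    ``positive_fraction`` defaults to 1:50, a desk-scale echo of the extreme
    screening imbalance (the full 1,186 : 549,879 ratio, about 1:464, is one
    config change away).  HU palettes follow standard radiology ranges:
    parenchyma about -850, nodules and vessels in the soft-tissue band, so
    nodule-vs-vessel discrimination is a shape problem, not a brightness one.
    """

    n_scans: int = 4
    slice_shape: tuple[int, int] = (256, 256)  # (rows, cols)
    n_slices: int = 40
    spacing_mm: tuple[float, float, float] = (0.7, 0.7, 2.5)  # (x, y, z)
    candidates_per_scan: int = 250
    positive_fraction: float = 1.0 / 51.0
    nodule_diameter_mm: tuple[float, float] = (3.0, 30.0)
    parenchyma_hu: tuple[float, float] = (-850.0, 60.0)  # mean, sd
    nodule_hu: tuple[float, float] = (40.0, 20.0)
    vessel_hu: tuple[float, float] = (30.0, 20.0)
    vessel_radius_mm: tuple[float, float] = (0.8, 2.0)
    vessel_aspect: tuple[float, float] = (3.0, 8.0)  # length / diameter
    vessel_fraction_of_negatives: float = 0.7
    n_readers: int = 4
    reader_detection_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.positive_fraction <= 0.5:
            raise ValueError("positive_fraction must be in (0, 0.5]")
        if self.nodule_diameter_mm[0] < 3.0:
            raise ValueError("nodules below 3 mm are not part of the reference standard")
        if self.n_scans < 1 or self.candidates_per_scan < 1:
            raise ValueError("n_scans and candidates_per_scan must be positive")
        if not 1 <= self.n_readers <= 4:
            raise ValueError("n_readers must be in 1..4")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d


#: in-plane margin (px) keeping candidate centres clear of slice edges, large
#: enough that the 91 px rotation context of augmentation always fits
_PLACEMENT_MARGIN = 48


def _lung_mask(shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = rows / 2.0, cols / 2.0
    a, b = rows * 0.40, cols * 0.44  # semi-axes
    return ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0


def _rim_mask(shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = rows / 2.0, cols / 2.0
    a, b = rows * 0.40, cols * 0.44
    r2 = ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2
    return (r2 > 1.0) & (r2 <= 1.18)


def _paint_vessel(vol, rng, cfg, lung2d, spacing_zyx):
    """Draw one cylindrical bright segment; returns its voxel coordinate list."""
    nz, ny, nx = vol.shape
    lo_r, hi_r = cfg.vessel_radius_mm
    radius = float(np.exp(rng.uniform(np.log(lo_r), np.log(hi_r))))  # calibres are log-spread
    aspect = rng.uniform(*cfg.vessel_aspect)
    # the painted shape is a capsule (centreline segment dilated by the
    # radius), so a segment of (aspect-1) diameters gives total elongation
    # `aspect`; aspect 1 degenerates to a sphere
    length = max(aspect - 1.0, 0.0) * 2.0 * radius
    for _ in range(50):
        r0 = rng.integers(_PLACEMENT_MARGIN, ny - _PLACEMENT_MARGIN)
        c0 = rng.integers(_PLACEMENT_MARGIN, nx - _PLACEMENT_MARGIN)
        if lung2d[r0, c0]:
            break
    else:
        return []
    z0 = rng.integers(2, nz - 2)
    direction = rng.normal(size=3)
    direction[0] *= 0.3  # vessels run mostly in-plane in this phantom
    direction /= np.linalg.norm(direction)
    start = np.array([z0, r0, c0], dtype=float) * spacing_zyx
    end = start + direction * length
    # bounding box in voxels, padded by the radius
    lo_mm = np.minimum(start, end) - (radius + 1.0)
    hi_mm = np.maximum(start, end) + (radius + 1.0)
    lo = np.maximum(np.floor(lo_mm / spacing_zyx).astype(int), 0)
    hi = np.minimum(np.ceil(hi_mm / spacing_zyx).astype(int) + 1, vol.shape)
    if np.any(hi - lo <= 0):
        return []
    zz, yy, xx = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    pts = np.stack([zz, yy, xx], axis=-1) * spacing_zyx
    seg = end - start
    seg_len2 = float(seg @ seg)
    if seg_len2 > 1e-9:
        t = np.clip(((pts - start) @ seg) / seg_len2, 0.0, 1.0)
    else:
        t = np.full(pts.shape[:-1], 0.5)
    closest = start + t[..., None] * seg
    dist = np.linalg.norm(pts - closest, axis=-1)
    w = 1.0 / (1.0 + np.exp((dist / radius - 1.0) / 0.12))
    mean, sd = cfg.vessel_hu
    tissue = rng.normal(mean, sd, size=w.shape)
    region = vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    region[...] = np.where(w > 0.02, (1 - w) * region + w * tissue, region)
    # the candidate centre hugs the centreline near the segment midpoint, the
    # way a detector would centre its proposal on the bright cross-section
    inside = (dist <= np.maximum(0.5 * radius, 0.8)) & lung2d[yy, xx]
    if not inside.any():
        return []
    coords = np.argwhere(inside) + lo
    centrality = dist[inside] + radius * np.abs(t[inside] - 0.5)
    order = np.argsort(centrality, kind="stable")
    return [tuple(int(v) for v in coords[i]) for i in order]


def _nodule_weight(pts_mm, center_mm, semi_axes_mm):
    r = np.linalg.norm((pts_mm - center_mm) / semi_axes_mm, axis=-1)
    return 1.0 / (1.0 + np.exp((r - 1.0) / 0.12))


def _paint_nodule(vol, rng, cfg, center_vox, semi_axes_mm, spacing_zyx):
    pad = semi_axes_mm.max() + 1.5
    center_mm = np.asarray(center_vox, dtype=float) * spacing_zyx
    lo = np.maximum(np.floor((center_mm - pad) / spacing_zyx).astype(int), 0)
    hi = np.minimum(np.ceil((center_mm + pad) / spacing_zyx).astype(int) + 1, vol.shape)
    zz, yy, xx = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    pts = np.stack([zz, yy, xx], axis=-1) * spacing_zyx
    w = _nodule_weight(pts, center_mm, semi_axes_mm)
    mean, sd = cfg.nodule_hu
    tissue = rng.normal(mean, sd, size=w.shape)
    region = vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    region[...] = np.where(w > 0.02, (1 - w) * region + w * tissue, region)


def generate_scan(
    config: PhantomConfig, scan_index: int
) -> tuple[CTVolume, list[Candidate], list[NoduleAnnotation]]:
    """Build one phantom scan with its candidates and per-reader annotations."""
    rng = np.random.default_rng([config.seed, scan_index])
    ny, nx = config.slice_shape
    nz = config.n_slices
    sx, sy, sz = config.spacing_mm
    spacing_zyx = np.array([sz, sy, sx])
    series_id = f"phantom-{config.seed}-{scan_index:03d}"

    lung2d = _lung_mask(config.slice_shape)
    rim2d = _rim_mask(config.slice_shape)

    vol = np.full((nz, ny, nx), -1000.0, dtype=np.float32)
    mean, sd = config.parenchyma_hu
    n_lung = int(lung2d.sum())
    for z in range(nz):
        vol[z][lung2d] = rng.normal(mean, sd, size=n_lung)
        vol[z][rim2d] = rng.normal(40.0, 15.0, size=int(rim2d.sum()))

    n_pos = int(np.floor(config.candidates_per_scan * config.positive_fraction + 0.5))
    n_neg = config.candidates_per_scan - n_pos

    # --- vessels -----------------------------------------------------------
    # one candidate per vessel, so no two negatives share a distractor and a
    # classifier cannot get by on memorising individual noise textures
    n_vessel_neg = int(round(n_neg * config.vessel_fraction_of_negatives))
    n_vessels = int(np.ceil(n_vessel_neg * 1.25)) + 4
    vessel_centres: list[list[tuple[int, int, int]]] = []
    for _ in range(n_vessels):
        coords = _paint_vessel(vol, rng, config, lung2d, spacing_zyx)
        if coords:
            vessel_centres.append(coords)

    # --- nodules -----------------------------------------------------------
    lo_d, hi_d = config.nodule_diameter_mm
    nodules: list[tuple[np.ndarray, np.ndarray]] = []  # (center_vox, semi_axes_mm)
    for _ in range(n_pos):
        diameter = float(np.exp(rng.uniform(np.log(lo_d), np.log(hi_d))))
        axes = (diameter / 2.0) * rng.uniform(0.9, 1.2, size=3)
        placed = False
        for _attempt in range(200):
            r = int(rng.integers(_PLACEMENT_MARGIN, ny - _PLACEMENT_MARGIN))
            c = int(rng.integers(_PLACEMENT_MARGIN, nx - _PLACEMENT_MARGIN))
            z = int(rng.integers(3, nz - 3))
            if not lung2d[r, c]:
                continue
            center = np.array([z, r, c], dtype=float)
            ok = True
            for other_center, other_axes in nodules:
                dist = np.linalg.norm((center - other_center) * spacing_zyx)
                if dist < axes.max() + other_axes.max() + 5.0:
                    ok = False
                    break
            if ok:
                placed = True
                break
        if not placed:
            raise GenerationError("could not place a nodule after 200 attempts")
        nodules.append((center, axes))
        _paint_nodule(vol, rng, config, center, axes, spacing_zyx)

    def inside_any_nodule(vox) -> bool:
        p_mm = np.asarray(vox, dtype=float) * spacing_zyx
        for center, axes in nodules:
            r = np.linalg.norm((p_mm - center * spacing_zyx) / axes)
            if r <= 1.5:
                return True
        return False

    volume = CTVolume(
        voxels=np.clip(np.round(vol), -1024, 3071).astype(np.int16),
        origin_mm=np.array([-nx * sx / 2.0, -ny * sy / 2.0, -nz * sz / 2.0]),
        spacing_mm=np.array([sx, sy, sz]),
        direction=np.eye(3),
    )

    # --- candidates --------------------------------------------------------
    candidates: list[Candidate] = []
    for center, _axes in nodules:
        world = voxel_to_world(volume, tuple(int(v) for v in center))
        candidates.append(Candidate(series_id=series_id, center=world, label=1))

    rim_edge = ndimage.binary_dilation(lung2d) & rim2d
    er, ec = np.nonzero(rim_edge)
    edge_ok = (
        (er >= _PLACEMENT_MARGIN) & (er < ny - _PLACEMENT_MARGIN)
        & (ec >= _PLACEMENT_MARGIN) & (ec < nx - _PLACEMENT_MARGIN)
    )
    rim_points = list(zip(er[edge_ok], ec[edge_ok]))

    picked: set[tuple[int, int, int]] = set()

    def usable(vox) -> bool:
        z, r, c = vox
        return (
            _PLACEMENT_MARGIN <= r < ny - _PLACEMENT_MARGIN
            and _PLACEMENT_MARGIN <= c < nx - _PLACEMENT_MARGIN
            and vox not in picked
            and not inside_any_nodule(vox)
        )

    neg_vox: list[tuple[int, int, int]] = []
    for coords in vessel_centres:
        if len(neg_vox) >= n_vessel_neg:
            break
        for vox in coords[:20]:  # most central voxels of this vessel
            if usable(vox):
                picked.add(vox)
                neg_vox.append(vox)
                break

    guard = 0
    while len(neg_vox) < n_neg and guard < n_neg * 80:
        guard += 1
        r, c = rim_points[rng.integers(len(rim_points))]
        vox = (int(rng.integers(2, nz - 2)), int(r), int(c))
        if usable(vox):
            picked.add(vox)
            neg_vox.append(vox)
    if len(neg_vox) < n_neg:
        raise GenerationError("could not sample enough negative candidates")
    for vox in neg_vox:
        world = voxel_to_world(volume, vox)
        candidates.append(Candidate(series_id=series_id, center=world, label=0))

    # --- per-reader annotations -------------------------------------------
    annotations: list[NoduleAnnotation] = []
    for center, axes in nodules:
        diameter = float(2.0 * axes.mean())
        center_world = voxel_to_world(volume, tuple(int(v) for v in center))
        base = center_world.as_array()
        for _reader in range(config.n_readers):
            if rng.random() >= config.reader_detection_prob:
                continue
            jitter = rng.uniform(-1.0, 1.0, size=3) * np.array([sx, sy, sz])
            annotations.append(
                NoduleAnnotation(
                    series_id=series_id,
                    center=WorldPoint(*(base + jitter)),
                    diameter_mm=diameter * float(rng.uniform(0.92, 1.08)),
                    reader_count=1,
                )
            )

    return volume, candidates, annotations


def generate_dataset(config: PhantomConfig, out_dir: str | os.PathLike) -> dict:
    """Write a LUNA16-layout directory: one .mhd/.raw pair per scan plus
    ``candidates.csv``, ``annotations.csv`` and a reproducibility manifest.

    Returns the manifest dictionary."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    all_candidates: list[Candidate] = []
    all_annotations: list[NoduleAnnotation] = []
    series_ids = []
    for scan_index in range(config.n_scans):
        volume, candidates, annotations = generate_scan(config, scan_index)
        series_id = candidates[0].series_id
        series_ids.append(series_id)
        write_metaimage(volume, os.path.join(out_dir, f"{series_id}.mhd"))
        all_candidates.extend(candidates)
        all_annotations.extend(annotations)
    write_candidates_csv(all_candidates, os.path.join(out_dir, "candidates.csv"))
    write_annotations_csv(all_annotations, os.path.join(out_dir, "annotations.csv"))
    manifest = {
        "config": config.to_dict(),
        "series_ids": series_ids,
        "n_candidates": len(all_candidates),
        "n_positive": sum(c.label for c in all_candidates),
        "n_annotations": len(all_annotations),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
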