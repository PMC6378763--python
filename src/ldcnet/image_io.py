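"""Reading and writing LUNA16-style data.

CT volumes travel as MetaImage pairs (a text ``.mhd`` header plus a raw voxel
payload); candidate and nodule-annotation tables are CSV files whose
coordinates are world-space millimetres.  This module also implements the
annotation post-processing used to build a nodule reference standard from
multiple readers: agglomerative merging of marks that lie closer than the sum
of their radii, and a consensus filter on the number of agreeing readers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "CTVolume",
    "WorldPoint",
    "NoduleAnnotation",
    "Candidate",
    "MetaImageError",
    "GeometryError",
    "read_metaimage",
    "write_metaimage",
    "world_to_voxel",
    "voxel_to_world",
    "merge_annotations",
    "consensus_filter",
    "read_candidates_csv",
    "write_candidates_csv",
    "read_annotations_csv",
    "write_annotations_csv",
]


class MetaImageError(IOError):
    """Raised when a MetaImage header is missing, inconsistent, or truncated."""


class GeometryError(ValueError):
    """Raised for degenerate spatial metadata (e.g. a singular direction matrix)."""


@dataclass
class CTVolume:
    """A CT volume in Hounsfield units with its spatial metadata.

    ``voxels`` is indexed ``(slice, row, col)``; ``origin_mm`` / ``spacing_mm``
    are ``(x, y, z)`` world-axis ordered, as in the MetaImage header, so
    ``col`` advances along world x, ``row`` along y and ``slice`` along z.
    """

    voxels: np.ndarray
    origin_mm: np.ndarray
    spacing_mm: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D array")
        if not np.all(self.spacing_mm > 0):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        norms = np.linalg.norm(self.direction, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("direction matrix rows must be unit-norm")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class WorldPoint:
    """A point in scanner (world) space, millimetres."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError("world coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class NoduleAnnotation:
    """One reader's mark (or a merged mark) for a nodule >= 3 mm."""

    series_id: str
    center: WorldPoint
    diameter_mm: float
    reader_count: int = 1

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")
        # 4 readers is the convention for this kind of reference standard, but
        # merged marks keep the exact constituent count so it is conserved.
        if self.reader_count < 1:
            raise ValueError("reader_count must be >= 1")


@dataclass(frozen=True)
class Candidate:
    """A screening location to be classified as nodule (1) or nonnodule (0)."""

    series_id: str
    center: WorldPoint
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


# ---------------------------------------------------------------------------
# MetaImage


def _parse_mhd_header(path: str) -> dict[str, str]:
    header: dict[str, str] = {}
    with open(path, "r") as fh:
        for line in fh:
            line = line.strip()
            if not line or "=" not in line:
                continue
            key, _, value = line.partition("=")
            header[key.strip()] = value.strip()
    return header


_ELEMENT_BYTES = {"MET_SHORT": 2, "MET_USHORT": 2, "MET_FLOAT": 4, "MET_DOUBLE": 8}


def _validate_mhd(path: str) -> None:
    """Check the declared geometry against the raw payload before handing the
    pair to SimpleITK, so failures name the offending header field."""
    if not os.path.exists(path):
        raise MetaImageError(f"header not found: {path}")
    header = _parse_mhd_header(path)
    for required in ("NDims", "DimSize", "ElementType", "ElementDataFile"):
        if required not in header:
            raise MetaImageError(f"header {path} missing field {required}")
    if header["NDims"] != "3":
        raise MetaImageError(f"NDims must be 3, got {header['NDims']}")
    try:
        dims = [int(tok) for tok in header["DimSize"].split()]
    except ValueError as exc:
        raise MetaImageError(f"unparsable DimSize {header['DimSize']!r}") from exc
    etype = header["ElementType"]
    if etype not in _ELEMENT_BYTES:
        raise MetaImageError(f"unsupported ElementType {etype}")
    if header.get("CompressedData", "False").lower() == "true":
        raise MetaImageError("CompressedData volumes are not supported")
    raw_path = os.path.join(os.path.dirname(path), header["ElementDataFile"])
    if not os.path.exists(raw_path):
        raise MetaImageError(f"ElementDataFile not found: {raw_path}")
    expected = int(np.prod(dims)) * _ELEMENT_BYTES[etype]
    actual = os.path.getsize(raw_path)
    if expected != actual:
        raise MetaImageError(
            f"DimSize {dims} with ElementType {etype} implies {expected} bytes "
            f"but {raw_path} holds {actual}"
        )


def read_metaimage(path: str | os.PathLike) -> CTVolume:
    """Read an uncompressed ``.mhd``/``.raw`` pair into a :class:`CTVolume`."""
    path = os.fspath(path)
    _validate_mhd(path)
    image = sitk.ReadImage(path)
    voxels = sitk.GetArrayFromImage(image)  # (slice, row, col)
    return CTVolume(
        voxels=voxels,
        origin_mm=np.array(image.GetOrigin()),
        spacing_mm=np.array(image.GetSpacing()),
        direction=np.array(image.GetDirection()).reshape(3, 3),
    )


def write_metaimage(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write *vol* as an uncompressed ``.mhd``/``.raw`` pair.

    Integer voxel arrays are stored as MET_SHORT, floating point as MET_FLOAT;
    both round-trip bit-exactly through :func:`read_metaimage`.
    """
    path = os.fspath(path)
    voxels = vol.voxels
    if np.issubdtype(voxels.dtype, np.integer):
        voxels = voxels.astype(np.int16)
    else:
        voxels = voxels.astype(np.float32)
    image = sitk.GetImageFromArray(voxels)
    image.SetOrigin(tuple(vol.origin_mm))
    image.SetSpacing(tuple(vol.spacing_mm))
    image.SetDirection(tuple(vol.direction.ravel()))
    sitk.WriteImage(image, path, useCompression=False)


# ---------------------------------------------------------------------------
# Coordinates


def _round_half_up(v: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(v, dtype=float) + 0.5).astype(int)


def world_to_voxel(vol: CTVolume, p: WorldPoint) -> tuple[int, int, int]:
    """Map a world-space point to the nearest ``(slice, row, col)`` index.

    The index may fall outside the voxel grid; callers decide whether that is
    an error.  Ties round half-up.
    """
    det = np.linalg.det(vol.direction)
    if abs(det) < 1e-12:
        raise GeometryError("direction matrix is singular")
    continuous = np.linalg.solve(vol.direction, p.as_array() - vol.origin_mm)
    continuous = continuous / vol.spacing_mm  # (x, y, z)
    ix, iy, iz = _round_half_up(continuous)
    return int(iz), int(iy), int(ix)


def voxel_to_world(vol: CTVolume, index: tuple[int, int, int]) -> WorldPoint:
    """Inverse of :func:`world_to_voxel` at exact voxel centres."""
    iz, iy, ix = index
    xyz = vol.direction @ (np.array([ix, iy, iz], dtype=float) * vol.spacing_mm)
    xyz = xyz + vol.origin_mm
    return WorldPoint(*xyz)


# ---------------------------------------------------------------------------
# Annotation merging and consensus


def merge_annotations(anns: list[NoduleAnnotation]) -> list[NoduleAnnotation]:
    """Merge reader marks that refer to the same nodule.

    Two marks belong together when their centres lie strictly closer than the
    sum of their radii; merging is transitive (a chain A~B~C collapses into
    one nodule even when A and C are far apart), i.e. nodules are the
    connected components of the pairwise closeness graph.  A merged mark sits
    at the arithmetic mean of its constituents' positions and carries the
    mean of their diameters — always averaged over the *original* marks, so
    the result does not depend on merge order.  Its ``reader_count`` is the
    total number of constituent marks (conserved across merging).  A
    singleton component returns its annotation unchanged.  Output order
    follows the input index of each component's first constituent.
    """
    if not anns:
        return []
    series = {a.series_id for a in anns}
    if len(series) > 1:
        raise ValueError(f"annotations span multiple series: {sorted(series)}")

    n = len(anns)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    centers = np.array([a.center.as_array() for a in anns])
    radii = np.array([a.diameter_mm for a in anns]) / 2.0
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(centers[i] - centers[j]) < radii[i] + radii[j]:
                parent[find(j)] = find(i)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)

    merged = []
    for members in sorted(components.values(), key=min):
        if len(members) == 1:
            merged.append(anns[members[0]])
            continue
        merged.append(
            NoduleAnnotation(
                series_id=anns[members[0]].series_id,
                center=WorldPoint(*centers[members].mean(axis=0)),
                diameter_mm=float(np.mean([anns[i].diameter_mm for i in members])),
                reader_count=sum(anns[i].reader_count for i in members),
            )
        )
    return merged


def consensus_filter(
    anns: list[NoduleAnnotation], min_readers: int
) -> list[NoduleAnnotation]:
    """Keep annotations agreed on by at least *min_readers* readers (1..4)."""
    if not 1 <= min_readers <= 4:
        raise ValueError("min_readers must be in 1..4")
    return [a for a in anns if a.reader_count >= min_readers]


# ---------------------------------------------------------------------------
# CSV dialects

_CAND_COLS = ["seriesuid", "coordX", "coordY", "coordZ", "class"]
_ANN_COLS = ["seriesuid", "coordX", "coordY", "coordZ", "diameter_mm"]


def read_candidates_csv(path: str | os.PathLike) -> list[Candidate]:
    """Read a LUNA16 candidates file (seriesuid, coordX/Y/Z, class)."""
    df = pd.read_csv(path)
    missing = [c for c in _CAND_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"candidates CSV missing column(s) {missing}")
    out: list[Candidate] = []
    for pos in range(len(df)):
        row = df.iloc[pos]
        cls = row["class"]
        if cls not in (0, 1):
            # +2: one for the header line, one for 1-based numbering
            raise ValueError(f"row {pos + 2}: class must be 0 or 1, got {cls!r}")
        out.append(
            Candidate(
                series_id=str(row["seriesuid"]),
                center=WorldPoint(
                    float(row["coordX"]), float(row["coordY"]), float(row["coordZ"])
                ),
                label=int(cls),
            )
        )
    return out


def write_candidates_csv(cands: list[Candidate], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [
            {
                "seriesuid": c.series_id,
                "coordX": c.center.x,
                "coordY": c.center.y,
                "coordZ": c.center.z,
                "class": c.label,
            }
            for c in cands
        ],
        columns=_CAND_COLS,
    ).to_csv(path, index=False)


def read_annotations_csv(path: str | os.PathLike) -> list[NoduleAnnotation]:
    """Read a LUNA16 annotations file (seriesuid, coordX/Y/Z, diameter_mm)."""
    df = pd.read_csv(path)
    missing = [c for c in _ANN_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"annotations CSV missing column(s) {missing}")
    return [
        NoduleAnnotation(
            series_id=str(r.seriesuid),
            center=WorldPoint(float(r.coordX), float(r.coordY), float(r.coordZ)),
            diameter_mm=float(r.diameter_mm),
        )
        for r in df.itertuples(index=False)
    ]


def write_annotations_csv(
    anns: list[NoduleAnnotation], path: str | os.PathLike
) -> None:
    pd.DataFrame(
        [
            {
                "seriesuid": a.series_id,
                "coordX": a.center.x,
                "coordY": a.center.y,
                "coordZ": a.center.z,
                "diameter_mm": a.diameter_mm,
            }
            for a in anns
        ],
        columns=_ANN_COLS,
    ).to_csv(path, index=False)
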