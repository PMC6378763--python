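"""Generate a small CT phantom dataset in the LUNA16 layout and look inside.

The phantom writes MetaImage volumes (.mhd/.raw) plus candidates.csv and
annotations.csv, exactly the files a real screening dataset would provide,
so every later stage runs without any download.
"""

import tempfile
from pathlib import Path

from ldcnet import PhantomConfig, generate_dataset, read_candidates_csv, read_metaimage
from ldcnet.image_io import read_annotations_csv

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp) / "phantom"
    config = PhantomConfig(n_scans=2, candidates_per_scan=100, seed=7)
    manifest = generate_dataset(config, out)

    print(f"scans written:       {manifest['series_ids']}")
    print(f"candidates:          {manifest['n_candidates']} "
          f"({manifest['n_positive']} nodules, imbalance ~1:"
          f"{manifest['n_candidates'] // max(manifest['n_positive'], 1) - 1})")
    print(f"reader annotations:  {manifest['n_annotations']}")

    volume = read_metaimage(out / f"{manifest['series_ids'][0]}.mhd")
    print(f"volume shape (slice,row,col): {volume.shape}, "
          f"spacing (x,y,z) mm: {tuple(volume.spacing_mm)}")
    print(f"HU range: [{volume.voxels.min()}, {volume.voxels.max()}] "
          "(air -1000, parenchyma ~-850, soft tissue ~+40)")

    candidates = read_candidates_csv(out / "candidates.csv")
    annotations = read_annotations_csv(out / "annotations.csv")
    print(f"first candidate row: series={candidates[0].series_id} "
          f"center=({candidates[0].center.x:.1f}, {candidates[0].center.y:.1f}, "
          f"{candidates[0].center.z:.1f}) mm, label={candidates[0].label}")
    print(f"first annotation:    diameter {annotations[0].diameter_mm:.1f} mm")
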