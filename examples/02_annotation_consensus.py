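"""Merge multi-reader nodule marks and apply a consensus filter.

Four simulated readers each mark nodules independently with a small
positional jitter.  Marks closer than the sum of their radii are merged
(transitively) into one nodule whose position and diameter are the averages
of the constituent marks; the consensus filter then keeps only nodules seen
by enough readers — the procedure that turns raw reader marks into a
reference standard.
"""

import tempfile
from pathlib import Path

from ldcnet import PhantomConfig, consensus_filter, generate_scan, merge_annotations

config = PhantomConfig(n_scans=1, candidates_per_scan=120, positive_fraction=0.1,
                       reader_detection_prob=0.75, seed=13)
_, candidates, annotations = generate_scan(config, 0)
n_nodules = sum(c.label for c in candidates)

print(f"true nodules in scan:      {n_nodules}")
print(f"raw reader marks:          {len(annotations)} "
      f"(4 readers x detection prob {config.reader_detection_prob})")

merged = merge_annotations(annotations)
print(f"after merging:             {len(merged)} distinct nodules")

for k in (1, 2, 3, 4):
    kept = consensus_filter(merged, k)
    print(f"  marked by >= {k} readers: {len(kept)}")

print("\nA consensus level of 3 of 4 readers is the usual quality bar for a")
print("positive reference standard; lower levels admit marks that only one")
print("or two readers believed were nodules.")
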