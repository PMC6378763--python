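"""Train LdcNet on a small phantom and evaluate it: the pipeline end to end.

synth -> extract (64 px patches, HU-normalised, edge-rejected) ->
augment (rotations/flips of nodules only) -> 60/20/20 candidate-level split
-> focal-loss training -> test-set metrics and ROC AUC.

This desk example uses a reduced phantom and a thinner network so it runs
in well under a minute on one CPU; scale it up by raising candidates_per_scan
and dropping the custom spec (see run_phantom_experiment's defaults).
"""

from ldcnet import NetworkSpec
from ldcnet.pipeline import run_phantom_experiment

spec = NetworkSpec(
    input_side=20, n_blocks=2, filters_per_block=[8, 16],
    kernel_per_block=[5, 3], fc_width=32,
)
result = run_phantom_experiment(
    seed=5,
    n_scans=2, candidates_per_scan=150, positive_fraction=0.1,
    loss="focal", gamma=2.5, alpha=0.5,
    epochs=8, input_scale=0.3125, batch_size=8,
    spec=spec,
)

print(f"candidates: {result['n_candidates']}  "
      f"(rejected near edges: {result['n_rejected']})")
print(f"training patches incl. augmented: {result['n_train_patches']}")
print(f"test set: {result['n_test']} candidates, "
      f"{result['n_test_positive']} nodules\n")
print(f"test accuracy:    {result['accuracy']:.3f}")
print(f"test sensitivity: {result['sensitivity']:.3f}   "
      "(fraction of nodules caught)")
print(f"test specificity: {result['specificity']:.3f}   "
      "(fraction of nonnodules passed)")
print(f"ROC AUC:          {result['auc']:.3f}")
print(f"validation accuracy stabilised at epoch "
      f"{result['stabilization_epoch']} of {len(result['history'])}")
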