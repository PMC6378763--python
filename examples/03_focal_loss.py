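"""How the focal loss reshapes cross-entropy for imbalanced screening data.

FL(p_t) = -alpha_t * (1 - p_t)^gamma * log(p_t).  The modulating factor
(1 - p_t)^gamma crushes the loss of easily classified samples, so the sea of
obvious negatives in a 1:464-imbalanced candidate list cannot drown out the
few hard nodules; alpha balances the two classes.
"""

import numpy as np

from ldcnet import FocalParams, Prediction, cross_entropy, focal

params = FocalParams(gamma=2.5, alpha=0.5)  # the best-performing setting
print(f"gamma={params.gamma}, alpha={params.alpha}\n")
print(f"{'p(nodule)':>10} {'truth':>6} {'CE':>9} {'FL':>10} {'FL/CE':>8}")
for p, y in [(0.02, -1), (0.3, -1), (0.6, -1),   # negatives, easy -> hard
             (0.95, 1), (0.6, 1), (0.1, 1)]:     # positives, easy -> hard
    pred = Prediction(p, y)
    ce = cross_entropy(pred)
    fl = focal(pred, params)
    print(f"{p:>10.2f} {y:>+6d} {ce:>9.4f} {fl:>10.6f} {fl / ce:>8.4f}")

print("\nAn easily classified negative (p=0.02) keeps a fraction ~1e-5 of its")
print("cross-entropy; a badly missed nodule (p=0.1) keeps almost half.  The")
print("gradient therefore concentrates on the rare, hard positives.")

# gamma = 0, alpha = 1 recovers the cross-entropy exactly
identity = FocalParams(gamma=0.0, alpha=1.0)
check = max(
    abs(focal(Prediction(p, 1), identity) - cross_entropy(Prediction(p, 1)))
    for p in np.linspace(0.01, 0.99, 99)
)
print(f"\nmax |FL(gamma=0, alpha=1) - CE| over a p-grid: {check:.2e}")
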