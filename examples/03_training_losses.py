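"""The segmentation training objective: binary cross-entropy + Dice loss +
propagation loss, on a toy slice where the prediction misses part of the
region that neighbouring slices vouch for.
"""

import numpy as np

from vertomics import LossWeights, bce_loss, combined_loss, dice_loss, propagation_loss

rng = np.random.default_rng(0)
n = 400
truth = np.zeros(n)
truth[:160] = 1  # ground-truth mask pixels
pred_label = np.zeros(n)
pred_label[:120] = 1  # prediction misses 40 truth pixels
pred_prob = np.clip(pred_label * 0.9 + 0.05 + rng.normal(0, 0.02, n), 0, 1)
prop = np.zeros(n)
prop[:150] = 1  # neighbouring slices imply 150 pixels

print(f"BCE          = {bce_loss(truth, pred_prob):.4f}")
print(f"Dice loss    = {dice_loss(truth, pred_label):.4f}  (1 - overlap coefficient)")
print(f"Propagation  = {propagation_loss(prop, pred_label):.4f}  (fraction of implied pixels missed)")
total = combined_loss(truth, pred_prob, pred_label, prop, LossWeights(1, 1, 1))
print(f"Combined     = {total:.4f}  (equal weights)")
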