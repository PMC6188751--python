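"""Evaluation metrics: Separability, bag AUC, LAA%, Spearman, Fisher, Dice.

The Separability example contrasts two classifiers that both classify the
bags correctly: f1 with near-chance instance posteriors and f2 with
confident ones.  S rewards f2 (0.4 vs 0.01) -- instance-level quality
without instance labels.
"""

import numpy as np

from emphymil.metrics import (
    bag_auc,
    compare_correlations_fisher,
    dice,
    laa_percentage,
    separability,
    spearman,
)
from emphymil.phantom import PhantomSpec, generate_subject

s_f1 = separability([[0.51, 0.49]], [[0.49, 0.49]])
s_f2 = separability([[0.9, 0.1]], [[0.1, 0.1]])
print(f"Separability: f1 = {s_f1:.2f} (barely better than chance), "
      f"f2 = {s_f2:.1f} (clear instance-level separation)")

auc = bag_auc([0.9, 0.4, 0.6, 0.1], [1, 1, -1, -1])
print(f"bag AUC of posteriors (0.9, 0.4 | 0.6, 0.1) = {auc}  "
      "(3 of 4 positive/negative pairs ranked correctly)")

subject = generate_subject(
    PhantomSpec(background_hu_sd=20.0, lesion_hu_sd=8.0, burden_target=0.2, seed=3),
    diseased=True,
)
laa = laa_percentage(subject.volume, subject.lung_mask)
print(f"density mask: LAA% at -950 HU = {laa:.1f} vs planted burden "
      f"{100 * subject.lesion_fraction:.1f}% of lung volume")

rho, p = spearman(np.array([1.0, 2, 3, 4, 5]), np.array([1.0, 3, 2, 5, 4]))
print(f"Spearman rho = {rho:.2f} (p = {p:.3f}, exact permutation for small n)")

z, p = compare_correlations_fisher(0.5, 103, 0.0, 103)
print(f"Fisher r-to-z comparison of rho=0.5 vs 0.0 (n=103 each): z = {z:.2f}, p = {p:.1e}")

a = np.zeros(200, bool); a[:100] = True
b = np.zeros(200, bool); b[75:175] = True
print(f"Dice of two 100-voxel masks overlapping in 25 = {dice(a, b):.2f}")
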