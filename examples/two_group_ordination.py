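"""Ordination of a dataset with a real between-group difference.

Simulates two groups whose compositions concentrate on disjoint clades of
the tree, computes every metric's distance matrix, and reports how far
apart the groups land on PC1 relative to the within-group spread (plus
the variance explained by the first two axes).
"""

import numpy as np

from unifracx import METRICS, distance_matrix, pcoa
from unifracx.synthdata import SyntheticSpec, simulate_two_group_dataset

spec = SyntheticSpec(n_samples=30, n_otus=120, effect_size=0.7,
                     depth_min=2000, depth_max=8000, seed=5)
tree, table, labels = simulate_two_group_dataset(spec)
labels = np.asarray(labels)
print(f"two-group dataset: {table.shape[0]} samples x {table.shape[1]} OTUs, "
      f"effect size {spec.effect_size}")

for metric in METRICS:
    dm = distance_matrix(tree, table, metric, seed=1)
    ordn = pcoa(dm)
    pc1 = ordn.axis(0)
    g1, g2 = pc1[labels == "group1"], pc1[labels == "group2"]
    gap = abs(g1.mean() - g2.mean()) / max(g1.std(), g2.std())
    pe = ordn.proportion_explained
    print(f"  {metric:12s} PC1/PC2 variance {100 * pe[0]:5.1f}% / {100 * pe[1]:4.1f}%   "
          f"group gap = {gap:4.1f} sd")
# gap = distance between group means on PC1 in units of the larger
# within-group standard deviation; values well above 1 mean clean
# separation. With a defined difference between groups, every weighting
# separates them — the metrics disagree mainly on structure-free data.
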