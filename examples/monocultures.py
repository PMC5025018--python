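"""Which metrics recognize near-monocultures?

Simulates three groups of 20 samples, each a taxa-shuffled copy of one
97%-dominated community with the dominant swapped to a group-specific
OTU, then asks each metric's distance matrix to recover the three groups
by average-linkage hierarchical clustering (adjusted Rand index; 1 =
perfect recovery, 0 = random).
"""

from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from unifracx import METRICS, distance_matrix
from unifracx.synthdata import monoculture_template, random_tree, simulate_monocultures

template = monoculture_template(seed=0)
dominants = list(template.index[:3])
table = simulate_monocultures(template, dominants, group_size=20, seed=1)
tree = random_tree(len(template), 2, names=list(template.index))
labels = [s.rsplit("_", 1)[0] for s in table.index]
print(f"monoculture table: {table.shape[0]} samples x {table.shape[1]} OTUs, "
      f"dominant at {template.max() / template.sum():.0%}")

for metric in METRICS:
    dm = distance_matrix(tree, table, metric, seed=3)
    z = linkage(squareform(dm.data, checks=False), method="average")
    ari = adjusted_rand_score(labels, fcluster(z, t=3, criterion="maxclust"))
    print(f"  {metric:12s} clustering ARI = {ari:5.2f}")
# Abundance-driven metrics (weighted, ratio, Bray-Curtis) separate the
# groups perfectly. Presence/absence (unweighted) sees only the shuffled 3%
# remainder; surprisal weighting (information) scores the 97% dominant near
# zero — both lose the monoculture identity.
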