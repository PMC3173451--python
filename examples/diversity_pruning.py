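"""Prune an environmental pool to a fixed budget by maximising Faith PD.

Bayesian tree inference cannot digest thousands of environmental homologs;
greedy maximum-PD selection keeps a small subset spanning as much branch
length (evolutionary history) of the pool as possible.
"""

import numpy as np

from mitoscreen import PruneConfig, faith_pd, greedy_pd_select
from mitoscreen.simulate import random_tree

rng = np.random.default_rng(11)
labels = [f"GOS_{i:03d}" for i in range(200)]
tree = random_tree(labels, rng)

k = 20
selection, trajectory = greedy_pd_select(tree, PruneConfig(target_size=k))
total = tree.total_branch_length()
print(f"pool of {len(labels)} sequences, total branch length {total:.2f}")
print(f"greedy selection of {k}: PD {trajectory[-1]:.2f} "
      f"({100 * trajectory[-1] / total:.0f}% of the total)")

random_pd = np.mean([
    faith_pd(tree, rng.choice(labels, size=k, replace=False).tolist())
    for _ in range(200)
])
print(f"mean PD of 200 random {k}-subsets: {random_pd:.2f}")
print("The greedy subset retains far more phylogenetic diversity than a")
print("random subsample of the same size, and on trees it is exactly optimal.")
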