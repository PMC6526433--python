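"""Exact binary k-means on a 1-D distance vector.

In one dimension with k = 2, every optimal clustering is a threshold
split of the sorted values, so the global optimum of the within-cluster
sum-of-squares objective is found by enumerating the N-1 splits — no
random initialization, no Lloyd iterations, fully deterministic.
"""

import numpy as np

from petspx import kmeans_binary_1d

rng = np.random.default_rng(0)
# 60 background-like distances plus 4 far outliers (the "tumor" cluster)
D = np.concatenate([rng.normal(300, 60, size=60), rng.normal(2200, 150, size=4)])

res = kmeans_binary_1d(D)
n_tumor = int(res.labels.sum())
print(f"split {len(D)} distances into {len(D) - n_tumor} normal + {n_tumor} tumor")
print(f"centroids: mu_normal = {res.mu_normal:.1f}, mu_tumor = {res.mu_tumor:.1f}")
print(f"within-cluster sum of squares (objective) = {res.inertia:.1f}")
print(f"separation = {res.separation:.1f} distance units")

# every tumor-cluster distance exceeds every normal-cluster one
assert D[res.labels == 1].min() >= D[res.labels == 0].max()
print("threshold between clusters:",
      f"({D[res.labels == 0].max():.1f}, {D[res.labels == 1].min():.1f})")
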