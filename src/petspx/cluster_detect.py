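"""Tumor recognition: exact binary k-means on the distance vector.

The per-superpixel L1 distances form a 1-D sample; splitting it into two
clusters minimizing within-cluster sum of squares is the k=2 k-means
objective. In one dimension every optimal 2-clustering is an interval
partition of the sorted values, so instead of Lloyd iterations from
random centroids the global optimum is found exactly by enumerating the
N-1 split points of the sorted vector with prefix sums (O(N log N)).
This removes seed sensitivity while optimizing the same objective. The
cluster with the larger centroid — superpixels far from the average —
is labeled tumor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .superpixel import SuperpixelPartition

NORMAL, TUMOR = 0, 1


@dataclass(frozen=True)
class ClusterResult:
    """Binary clustering of the distance vector.

    ``labels[i]`` is TUMOR (1) or NORMAL (0) for superpixel i.
    ``separation`` is mu_tumor - mu_normal (> 0 by construction);
    ``tumor_detected`` is False only when the optional separation guard
    rejected the split, in which case all labels are NORMAL.
    """

    labels: np.ndarray = field(repr=False)
    mu_normal: float
    mu_tumor: float
    inertia: float
    separation: float
    tumor_detected: bool = True

    @property
    def centroids(self) -> tuple[float, float]:
        return (self.mu_normal, self.mu_tumor)


def _best_split(x_sorted: np.ndarray) -> tuple[int, float]:
    """Optimal split index t (lower cluster = first t values) and its cost."""
    n = len(x_sorted)
    csum = np.cumsum(x_sorted)
    csq = np.cumsum(x_sorted**2)
    t = np.arange(1, n)
    sum_lo, sq_lo = csum[t - 1], csq[t - 1]
    sum_hi, sq_hi = csum[-1] - sum_lo, csq[-1] - sq_lo
    cost = (sq_lo - sum_lo**2 / t) + (sq_hi - sum_hi**2 / (n - t))
    best = int(np.argmin(cost))
    return best + 1, float(cost[best])


def kmeans_binary_1d(
    D: np.ndarray, seed: int = 0, min_separation: float = 0.0
) -> ClusterResult:
    """Exact two-cluster k-means of a 1-D distance vector.

    Parameters
    ----------
    D
        Non-negative distance per superpixel, length N >= 2.
    seed
        Unused (the solver is deterministic); kept for interface
        compatibility with stochastic k-means drivers.
    min_separation
        Optional guard in pooled-standard-deviation units: if the
        centroid gap is below ``min_separation * std(D)`` the split is
        rejected and the result reports no tumor. 0 disables the guard
        (a split is always produced).

    Raises
    ------
    DegenerateInputError
        If D is constant (no separable structure).
    """
    del seed
    D = np.asarray(D, dtype=np.float64)
    n = len(D)
    if n < 2:
        raise ValidationError(f"need at least 2 superpixels to cluster, got {n}")
    if np.ptp(D) == 0.0:
        raise DegenerateInputError(
            "distance vector is constant: no separable structure for a binary split"
        )
    order = np.argsort(D, kind="stable")
    x = D[order]
    t, inertia = _best_split(x)
    mu_normal = float(x[:t].mean())
    mu_tumor = float(x[t:].mean())
    labels = np.full(n, NORMAL, dtype=np.int8)
    labels[order[t:]] = TUMOR
    separation = mu_tumor - mu_normal
    if min_separation > 0.0 and separation < min_separation * float(D.std()):
        return ClusterResult(
            labels=np.full(n, NORMAL, dtype=np.int8),
            mu_normal=float(D.mean()),
            mu_tumor=float(D.mean()),
            inertia=float(((D - D.mean()) ** 2).sum()),
            separation=separation,
            tumor_detected=False,
        )
    return ClusterResult(
        labels=labels,
        mu_normal=mu_normal,
        mu_tumor=mu_tumor,
        inertia=inertia,
        separation=separation,
    )


def tumor_superpixels(
    result: ClusterResult, partition: SuperpixelPartition
) -> np.ndarray:
    """Labels of superpixels in the tumor cluster, ascending."""
    if len(result.labels) != partition.n_superpixels:
        raise ValidationError(
            f"cluster result has {len(result.labels)} superpixels, "
            f"partition has {partition.n_superpixels}"
        )
    return np.flatnonzero(result.labels == TUMOR)
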