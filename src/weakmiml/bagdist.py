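"""Hausdorff distances between bags and PAM k-medoids clustering over them.

Bags are compared through nearest-instance Euclidean distances:

* average Hausdorff: (Σ_{a∈A} min_b ‖a−b‖ + Σ_{b∈B} min_a ‖a−b‖) / (|A|+|B|)
* maximum Hausdorff: max(max_a min_b ‖a−b‖, max_b min_a ‖a−b‖)

Both are symmetric, zero iff each bag's instances all coincide with
instances of the other, and reduce to the Euclidean distance for singleton
bags. k-medoids uses the classic PAM greedy-swap heuristic over a cached
bag-distance matrix; given the seed it is fully deterministic, with ties
broken toward the lowest index.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def _check_pair(A, B):
    a = np.atleast_2d(np.asarray(A.instances if hasattr(A, "instances") else A, float))
    b = np.atleast_2d(np.asarray(B.instances if hasattr(B, "instances") else B, float))
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"instance dimension mismatch: {a.shape[1]} vs {b.shape[1]}"
        )
    return a, b


def avg_hausdorff(A, B) -> float:
    """Average Hausdorff distance between two bags."""
    a, b = _check_pair(A, B)
    d = cdist(a, b)
    return float((d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(a) + len(b)))


def max_hausdorff(A, B) -> float:
    """Maximum (classic) Hausdorff distance between two bags."""
    a, b = _check_pair(A, B)
    d = cdist(a, b)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def pairwise_bag_distances(bags_a, bags_b=None, metric: str = "avg") -> np.ndarray:
    """Distance matrix between two bag collections (or one against itself).

    Computes a single instance-level distance matrix and reduces per bag
    pair, which is much faster than looping ``avg_hausdorff`` for the
    dataset-scale matrices the embedding and cross-validation need.
    """
    if metric not in ("avg", "max"):
        raise ValueError(f"unknown metric {metric!r}")
    symmetric = bags_b is None
    if symmetric:
        bags_b = bags_a
    xa = [np.asarray(b.instances, float) for b in bags_a]
    xb = [np.asarray(b.instances, float) for b in bags_b]
    dims = {x.shape[1] for x in xa} | {x.shape[1] for x in xb}
    if len(dims) != 1:
        raise ValueError(f"instance dimension mismatch across bags: {sorted(dims)}")
    offs_a = np.cumsum([0] + [len(x) for x in xa])
    offs_b = np.cumsum([0] + [len(x) for x in xb])
    big = cdist(np.vstack(xa), np.vstack(xb))
    out = np.zeros((len(xa), len(xb)))
    for i in range(len(xa)):
        block_rows = big[offs_a[i] : offs_a[i + 1]]
        j_start = i if symmetric else 0
        for j in range(j_start, len(xb)):
            d = block_rows[:, offs_b[j] : offs_b[j + 1]]
            if metric == "avg":
                v = (d.min(axis=1).sum() + d.min(axis=0).sum()) / (
                    d.shape[0] + d.shape[1]
                )
            else:
                v = max(d.min(axis=1).max(), d.min(axis=0).max())
            out[i, j] = v
            if symmetric:
                out[j, i] = v
    return out


def _assignment_cost(D: np.ndarray, medoids: np.ndarray) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def k_medoids(
    bags=None,
    K: int = 1,
    seed: int = 0,
    D: np.ndarray | None = None,
    max_sweeps: int = 100,
) -> list:
    """PAM k-medoids over average-Hausdorff bag distances.

    Seeded random initialization followed by greedy swaps (the best
    improving (medoid, non-medoid) exchange per sweep) until no swap lowers
    the total nearest-medoid cost or ``max_sweeps`` is reached. A
    precomputed distance matrix ``D`` may be supplied to skip the Hausdorff
    computation. Returns sorted medoid indices.
    """
    if D is None:
        D = pairwise_bag_distances(bags)
    m = D.shape[0]
    if not (1 <= K <= m):
        raise ValueError(f"K must be in [1, {m}], got {K}")
    rng = np.random.default_rng(seed)
    medoids = np.sort(rng.choice(m, size=K, replace=False))
    if K == m:
        return list(range(m))

    for _ in range(max_sweeps):
        sub = D[:, medoids]
        order = np.argsort(sub, axis=1, kind="stable")
        nearest = order[:, 0]
        d1 = sub[np.arange(m), nearest]
        if K > 1:
            d2 = sub[np.arange(m), order[:, 1]]
        else:
            d2 = np.full(m, np.inf)
        cost = d1.sum()
        non_medoids = np.setdiff1d(np.arange(m), medoids)
        best = (0.0, None, None)  # (improvement, medoid position, candidate)
        for pos in range(K):
            # distances to the closest *remaining* medoid if medoid `pos` leaves
            base = np.where(nearest == pos, d2, d1)
            # cost of each candidate swap, vectorized over candidates
            cand_cost = np.minimum(D[:, non_medoids], base[:, None]).sum(axis=0)
            k_best = int(np.argmin(cand_cost))
            improvement = cost - cand_cost[k_best]
            if improvement > best[0] + 1e-12:
                best = (improvement, pos, non_medoids[k_best])
        if best[1] is None:
            break
        medoids = medoids.copy()
        medoids[best[1]] = best[2]
        medoids = np.sort(medoids)
    return [int(i) for i in medoids]
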