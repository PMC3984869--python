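"""k-medoids partitioning on a precomputed dissimilarity matrix.

PAM-style: a greedy BUILD initialization followed by alternating
assign/update refinement, entirely on the distance matrix, so it works with
any metric (here: DTW over prototypes, ED over raw or PAA-reduced series).
Deterministic with ``init="pam-build"``; ``init="random"`` draws the initial
medoids from a seeded generator for multi-restart experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

__all__ = ["KMedoidsParams", "KMedoidsResult", "k_medoids"]


@dataclass(frozen=True)
class KMedoidsParams:
    k: int
    init: str = "pam-build"
    seed: Optional[int] = None
    max_iter: int = 300

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.init not in ("pam-build", "random"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class KMedoidsResult:
    medoids: np.ndarray        # (k,) object indices
    assignment: np.ndarray     # (N,) cluster index in 0..k-1
    cost: float                # sum of distances to assigned medoids
    cost_history: List[float] = field(default_factory=list)
    n_iter: int = 0


def _pam_build(dist: np.ndarray, k: int) -> np.ndarray:
    """Greedy BUILD: first medoid minimizes its row sum; each next medoid
    maximizes the total decrease in assignment cost. Ties break low."""
    n = dist.shape[0]
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    dnear = dist[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(dnear[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        dnear = np.minimum(dnear, dist[c])
    return np.array(sorted(medoids), dtype=np.int64)


def k_medoids(dist: np.ndarray, params: KMedoidsParams) -> KMedoidsResult:
    """Partition the objects of a distance matrix around ``k`` medoids.

    PAM-style SWAP refinement: starting from the initial medoid set, the
    single medoid-for-nonmedoid exchange that lowers the total assignment
    cost the most is applied, repeatedly, until no exchange improves the
    cost or ``max_iter`` swaps have been made. Cost is strictly decreasing
    across swaps, so the final medoid set is a fixed point of the exchange
    neighborhood.
    """
    dist = np.asarray(dist, dtype=np.float64)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if params.k > n:
        raise ValueError(f"k={params.k} exceeds the number of objects {n}")

    if params.init == "pam-build":
        medoids = _pam_build(dist, params.k)
    else:
        rng = np.random.default_rng(params.seed)
        medoids = np.sort(rng.choice(n, size=params.k, replace=False)).astype(np.int64)

    cost = float(dist[medoids].min(axis=0).sum())
    history: List[float] = [cost]
    for _ in range(params.max_iter):
        best_cost, best_swap = cost, None
        for mi in range(params.k):
            others = np.delete(medoids, mi)
            base = (
                dist[others].min(axis=0)
                if others.size
                else np.full(n, np.inf)
            )
            # cost after swapping medoid mi for each candidate, vectorized
            cand_costs = np.minimum(base[None, :], dist).sum(axis=1)
            cand_costs[medoids] = np.inf
            c = int(np.argmin(cand_costs))
            if cand_costs[c] < best_cost - 1e-12:
                best_cost, best_swap = float(cand_costs[c]), (mi, c)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
        medoids = np.sort(medoids)
        cost = best_cost
        history.append(cost)

    assignment = np.argmin(dist[medoids], axis=0)
    # a medoid always belongs to its own cluster even under distance ties
    for ci, m in enumerate(medoids):
        assignment[m] = ci
    return KMedoidsResult(
        medoids=medoids,
        assignment=assignment.astype(np.int64),
        cost=cost,
        cost_history=history,
        n_iter=len(history) - 1,
    )
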