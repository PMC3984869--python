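"""Affinity-search subclustering (CAST) and prototype construction.

Step 1 of the two-step clustering: series are grouped into subclusters of
mutually similar-in-time members using the cluster affinity search technique,
then each subcluster is condensed into a single prototype series weighted by
member affinities. The subcluster count M is controlled indirectly by the
affinity threshold alpha, not given in advance.

The affinity of a series x to a subcluster SC is the mean similarity of x to
the current members, a(x) = sum_{y in SC} A_xy / |SC|. For a member, the sum
includes its own self-similarity A_xx = 1 (so a singleton's seed has affinity
1 and is never self-expelled); for an outside candidate it runs over members
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .dataset import TimeSeriesDataset

__all__ = [
    "CastParams",
    "SubCluster",
    "SubClustering",
    "affinity",
    "cast_subcluster",
    "build_prototype",
    "alpha_for_target_subclusters",
]


@dataclass(frozen=True)
class CastParams:
    """Parameters of the affinity subclustering step.

    alpha : affinity threshold in (0, 1). Higher values demand tighter
        subclusters, so M grows with alpha.
    max_sweeps : cap on add/remove sweeps per subcluster; the loop normally
        stops when a full sweep changes nothing.
    """

    alpha: float = 0.8
    max_sweeps: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")


@dataclass
class SubCluster:
    """A group of similar-in-time series with per-member affinities and,
    once built, a prototype series."""

    member_ids: List[int]
    affinities: Dict[int, float]
    prototype: Optional[np.ndarray] = None


@dataclass
class SubClustering:
    """A partition of the dataset into M affinity subclusters."""

    subclusters: List[SubCluster]

    @property
    def m(self) -> int:
        return len(self.subclusters)

    def assignment(self, n_series: int) -> np.ndarray:
        """(N,) array mapping each series index to its subcluster index."""
        out = np.full(n_series, -1, dtype=np.int64)
        for j, sc in enumerate(self.subclusters):
            out[np.asarray(sc.member_ids, dtype=np.int64)] = j
        if np.any(out < 0):
            raise ValueError("subclustering does not cover the dataset")
        return out

    def prototypes(self) -> np.ndarray:
        """(M, n) matrix of prototype series."""
        if any(sc.prototype is None for sc in self.subclusters):
            raise ValueError("prototypes not built")
        return np.vstack([sc.prototype for sc in self.subclusters])


def affinity(x: int, members: List[int], similarity: np.ndarray) -> float:
    """Mean similarity of series ``x`` to the members of a subcluster."""
    if not members:
        raise ValueError("affinity to an empty subcluster is undefined")
    return float(similarity[x, members].sum() / len(members))


def cast_subcluster(similarity: np.ndarray, params: CastParams) -> SubClustering:
    """Partition all series into affinity subclusters.

    Subclusters are grown one at a time: a new one opens with the unassigned
    series of highest total similarity to the other unassigned series, then
    alternates an ADD phase (admit the unassigned series of maximal affinity
    while that affinity >= alpha) and a REMOVE phase (expel the member of
    minimal affinity while that affinity < alpha, re-evaluating after each
    expulsion, never emptying the subcluster) until a full sweep changes
    nothing. All ties break toward the lowest series index, so the result is
    deterministic. Per-member affinities at closing time are stored; they are
    the prototype weights.
    """
    A = np.asarray(similarity, dtype=np.float64)
    n = A.shape[0]
    if A.shape != (n, n):
        raise ValueError("similarity matrix must be square")
    alpha = params.alpha
    unassigned = np.ones(n, dtype=bool)
    subclusters: List[SubCluster] = []

    while unassigned.any():
        open_ids = np.flatnonzero(unassigned)
        # seed: highest similarity row-sum over the unassigned block
        row_sums = A[np.ix_(open_ids, open_ids)].sum(axis=1)
        seed = int(open_ids[int(np.argmax(row_sums))])

        in_sc = np.zeros(n, dtype=bool)
        in_sc[seed] = True
        size = 1
        # sims[x] = sum of similarities from x to current members
        sims = A[:, seed].copy()
        changed = True
        sweeps = 0
        while changed:
            sweeps += 1
            if sweeps > params.max_sweeps:
                warnings.warn(
                    "max_sweeps exhausted; closing subcluster as-is",
                    RuntimeWarning,
                    stacklevel=2,
                )
                break
            changed = False
            # ADD: admit best unassigned outsider while its affinity >= alpha
            while True:
                cand = unassigned & ~in_sc
                ids = np.flatnonzero(cand)
                if ids.size == 0:
                    break
                aff = sims[ids] / size
                best = int(np.argmax(aff))
                if aff[best] < alpha:
                    break
                x = int(ids[best])
                in_sc[x] = True
                size += 1
                sims += A[:, x]
                changed = True
            # REMOVE: expel worst member while its affinity < alpha
            while size > 1:
                ids = np.flatnonzero(in_sc)
                aff = sims[ids] / size
                worst = int(np.argmin(aff))
                if aff[worst] >= alpha:
                    break
                x = int(ids[worst])
                in_sc[x] = False
                size -= 1
                sims -= A[:, x]
                changed = True

        members = [int(i) for i in np.flatnonzero(in_sc)]
        affs = {x: float(sims[x] / size) for x in members}
        subclusters.append(SubCluster(member_ids=members, affinities=affs))
        unassigned[in_sc] = False

    return SubClustering(subclusters)


def build_prototype(
    sc: SubCluster, dataset: TimeSeriesDataset, normalize: str = "count"
) -> np.ndarray:
    """Affinity-weighted prototype of a subcluster.

    The default is the literal count-normalized combination
    ``r = sum_y a(F_y) * F_y / |SC|``; with affinities below 1 this shrinks
    the prototype toward 0, which is harmless to the rank-based merge step.
    ``normalize="affinity"`` divides by the total affinity mass instead,
    giving a true weighted mean.
    """
    members = sc.member_ids
    try:
        w = np.array([sc.affinities[x] for x in members], dtype=np.float64)
    except KeyError as exc:
        raise ValueError(f"missing affinity for member {exc.args[0]}") from exc
    data = dataset.values[np.asarray(members, dtype=np.int64)]
    if normalize == "count":
        denom = len(members)
    elif normalize == "affinity":
        denom = w.sum()
    else:
        raise ValueError(f"unknown prototype normalization {normalize!r}")
    return (w[:, None] * data).sum(axis=0) / denom


def build_all_prototypes(
    subclustering: SubClustering, dataset: TimeSeriesDataset, normalize: str = "count"
) -> SubClustering:
    """Fill in the prototype of every subcluster in place; returns the input."""
    for sc in subclustering.subclusters:
        sc.prototype = build_prototype(sc, dataset, normalize=normalize)
    return subclustering


def alpha_for_target_subclusters(
    similarity: np.ndarray,
    target_m: int,
    max_sweeps: int = 100,
    iterations: int = 20,
) -> Tuple[float, SubClustering]:
    """Binary-search the affinity threshold toward a desired subcluster count.

    Exploits the monotone trend of M versus alpha (higher thresholds produce
    more, tighter subclusters). Returns the threshold and subclustering whose
    M came closest to ``target_m`` across the search.
    """
    lo, hi = 1e-6, 1.0 - 1e-6
    best: Tuple[float, SubClustering] | None = None
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        sub = cast_subcluster(similarity, CastParams(alpha=mid, max_sweeps=max_sweeps))
        if best is None or abs(sub.m - target_m) < abs(best[1].m - target_m):
            best = (mid, sub)
        if sub.m == target_m:
            break
        if sub.m < target_m:
            lo = mid
        else:
            hi = mid
    assert best is not None
    return best
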