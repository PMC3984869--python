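"""The two-step clustering pipeline and the conventional k-medoids baselines.

Step 1 groups z-normalized series into affinity subclusters on Euclidean
similarity and condenses each into a prototype; step 2 computes the DTW
distance matrix over the (few) prototypes, partitions the prototypes with
k-medoids, and lets every series inherit the cluster of its subcluster's
prototype. The expensive elastic measure therefore only ever touches an
M x M problem with M << N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cast import (
    CastParams,
    SubClustering,
    alpha_for_target_subclusters,
    build_all_prototypes,
    cast_subcluster,
)
from .dataset import TimeSeriesDataset
from .distances import distance_to_similarity, paa_transform, pairwise_matrix
from .kmedoids import KMedoidsParams, KMedoidsResult, k_medoids

__all__ = ["TTCRun", "prototype_matrix", "ttc_cluster", "baseline_kmedoids"]


def prototype_matrix(
    subclustering: SubClustering,
    normalize_by_path: bool = False,
    window: Optional[int] = None,
) -> np.ndarray:
    """M x M DTW distance matrix over the subcluster prototypes."""
    return pairwise_matrix(
        subclustering.prototypes(),
        metric="dtw",
        normalize_by_path=normalize_by_path,
        window=window,
    )


@dataclass
class TTCRun:
    """Everything one pipeline run produced."""

    assignment: np.ndarray          # (N,) final cluster index per series
    k: int
    subclustering: SubClustering
    prototype_distances: np.ndarray
    kmedoids: KMedoidsResult
    alpha: float


def ttc_cluster(
    dataset: TimeSeriesDataset,
    cast_params: CastParams,
    km_params: KMedoidsParams,
    normalize: bool = True,
    similarity: str = "pearson",
    prototype_normalize: str = "count",
    dtw_normalize_by_path: bool = False,
    dtw_window: Optional[int] = None,
    target_subclusters: Optional[int] = None,
) -> TTCRun:
    """Run the full two-step pipeline on a dataset.

    z-normalize -> pairwise ED -> similarity -> affinity subclustering ->
    prototypes -> pairwise DTW over prototypes -> k-medoids -> inherit the
    prototype's cluster. ``target_subclusters`` replaces the fixed affinity
    threshold by a binary search for the threshold whose subcluster count
    comes closest to the target.
    """
    work = dataset.z_normalized() if normalize else dataset
    dist = pairwise_matrix(work.values, metric="ed")
    sim = distance_to_similarity(dist, method=similarity, length=work.length)
    if target_subclusters is not None:
        alpha, sub = alpha_for_target_subclusters(
            sim, target_subclusters, max_sweeps=cast_params.max_sweeps
        )
    else:
        alpha = cast_params.alpha
        sub = cast_subcluster(sim, cast_params)
    if km_params.k > sub.m:
        raise ValueError(
            f"k={km_params.k} exceeds the number of subclusters M={sub.m}; "
            "lower the affinity threshold or ask for fewer clusters"
        )
    build_all_prototypes(sub, work, normalize=prototype_normalize)
    proto_dist = prototype_matrix(
        sub, normalize_by_path=dtw_normalize_by_path, window=dtw_window
    )
    km = k_medoids(proto_dist, km_params)
    assignment = km.assignment[sub.assignment(dataset.n_series)]
    return TTCRun(
        assignment=assignment,
        k=km_params.k,
        subclustering=sub,
        prototype_distances=proto_dist,
        kmedoids=km,
        alpha=alpha,
    )


def baseline_kmedoids(
    dataset: TimeSeriesDataset,
    km_params: KMedoidsParams,
    representation: str = "raw-ed",
    paa_ratios: Sequence[int] = (4, 6, 8),
    normalize: bool = True,
    restarts: int = 0,
) -> "list[KMedoidsResult]":
    """Conventional k-medoids over the full N x N Euclidean matrix.

    representation : {"raw-ed", "paa-ed"}
        ``raw-ed`` clusters the (z-normalized) raw series; ``paa-ed``
        clusters each PAA reduction in ``paa_ratios`` and returns one result
        per ratio (scores are conventionally averaged across ratios).
    restarts : number of extra random-init runs; the best-cost result per
        representation is kept.
    """
    work = dataset.z_normalized() if normalize else dataset
    if representation == "raw-ed":
        mats = [pairwise_matrix(work.values, metric="ed")]
    elif representation == "paa-ed":
        mats = [
            pairwise_matrix(paa_transform(work.values, r), metric="ed")
            for r in paa_ratios
        ]
    else:
        raise ValueError(f"unknown representation {representation!r}")

    results = []
    for dist in mats:
        best = k_medoids(dist, km_params)
        base_seed = 0 if km_params.seed is None else km_params.seed
        for r in range(restarts):
            alt = k_medoids(
                dist,
                KMedoidsParams(
                    k=km_params.k,
                    init="random",
                    seed=base_seed + r,
                    max_iter=km_params.max_iter,
                ),
            )
            if alt.cost < best.cost:
                best = alt
        results.append(best)
    return results
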