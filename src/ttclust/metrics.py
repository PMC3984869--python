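"""External cluster-validity indices and reduction-step accounting.

Rand Index and converse entropy score a final clustering against ground-truth
class labels; the reduction factor and majority-class error rate quantify how
much the affinity subclustering step shrinks the dataset and how much label
purity it gives up in doing so. ``instruction_count`` is the arithmetic cost
of filling a full pairwise Euclidean distance matrix, the quantity the
prototype reduction exists to avoid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .cast import SubClustering

__all__ = [
    "EvaluationReport",
    "pair_counts",
    "rand_index",
    "cluster_entropy",
    "con_entropy",
    "reduction_factor",
    "error_rate",
    "instruction_count",
]


@dataclass
class EvaluationReport:
    """All evaluation statistics of one clustering run."""

    rand_index: Optional[float] = None
    con_entropy: Optional[float] = None
    per_cluster_entropy: Optional[List[float]] = None
    pair_counts: Optional[Dict[str, int]] = None
    reduction_factor: Optional[float] = None
    error_rate: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "rand_index": self.rand_index,
            "con_entropy": self.con_entropy,
            "per_cluster_entropy": self.per_cluster_entropy,
            "pair_counts": self.pair_counts,
            "reduction_factor": self.reduction_factor,
            "error_rate": self.error_rate,
        }


def _check_same_ids(pred: np.ndarray, truth: np.ndarray) -> None:
    if pred.shape != truth.shape:
        raise ValueError("clustering and ground truth must cover the same series")


def pair_counts(pred: Sequence[int], truth: Sequence[int]) -> Dict[str, int]:
    """TP/TN/FP/FN pair counts between a clustering and the ground truth.

    TP: pairs together in both; TN: apart in both; FP: together in the
    clustering only; FN: together in the ground truth only. The four counts
    always sum to N(N-1)/2.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    _check_same_ids(pred, truth)
    n = pred.size
    # contingency table of (cluster, class) co-occupancy
    _, pi = np.unique(pred, return_inverse=True)
    _, ti = np.unique(truth, return_inverse=True)
    table = np.zeros((pi.max() + 1, ti.max() + 1), dtype=np.int64)
    np.add.at(table, (pi, ti), 1)

    def _c2(a: np.ndarray) -> int:
        return int((a * (a - 1) // 2).sum())

    total = n * (n - 1) // 2
    tp = _c2(table)
    same_pred = _c2(table.sum(axis=1))
    same_truth = _c2(table.sum(axis=0))
    fp = same_pred - tp
    fn = same_truth - tp
    tn = total - tp - fp - fn
    return {"TP": tp, "TN": tn, "FP": fp, "FN": fn}


def rand_index(pred: Sequence[int], truth: Sequence[int]) -> float:
    """Fraction of series pairs on which clustering and ground truth agree:
    RI = (TP + TN) / (TP + TN + FP + FN), in [0, 1], 1 iff identical
    partitions."""
    c = pair_counts(pred, truth)
    total = c["TP"] + c["TN"] + c["FP"] + c["FN"]
    if total == 0:
        return 1.0
    return (c["TP"] + c["TN"]) / total


def cluster_entropy(member_classes: Sequence[int], h: int) -> float:
    """Normalized Shannon entropy of the class distribution inside one
    cluster: 0 for a pure cluster, 1 for a uniform spread over all ``h``
    classes. With ``h < 2`` the ground truth has a single class and the
    entropy is defined as 0. The log base cancels in the normalization;
    natural log is used."""
    if h < 2:
        return 0.0
    classes = np.asarray(member_classes)
    if classes.size == 0:
        raise ValueError("empty cluster")
    _, counts = np.unique(classes, return_counts=True)
    p = counts / classes.size
    ent = float(-(p * np.log(p)).sum())
    return ent / np.log(h)


def con_entropy(pred: Sequence[int], truth: Sequence[int]) -> float:
    """Converse entropy: 1 minus the size-weighted mean of per-cluster
    normalized entropies; 1 when clustering and ground truth coincide."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    _check_same_ids(pred, truth)
    h = int(np.unique(truth).size)
    n = pred.size
    acc = 0.0
    for c in np.unique(pred):
        mask = pred == c
        acc += mask.sum() * cluster_entropy(truth[mask], h)
    return 1.0 - acc / n


def per_cluster_entropies(pred: Sequence[int], truth: Sequence[int]) -> List[float]:
    """Normalized entropy of each cluster, in cluster-index order."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    h = int(np.unique(truth).size)
    return [cluster_entropy(truth[pred == c], h) for c in np.unique(pred)]


def reduction_factor(m: int, n: int) -> float:
    """R_factor = M/N, the subcluster count relative to the dataset size;
    a value of 0.23 means the merge step sees 77% less data."""
    if not 1 <= m <= n:
        raise ValueError("need 1 <= M <= N")
    return m / n


def error_rate(subclustering: SubClustering, truth: Sequence[int]) -> float:
    """Size-weighted majority-class misclassification rate of the reduction
    step.

    Each subcluster is assigned its most frequent ground-truth class (ties
    break toward the lowest class id); its error is the fraction of members
    outside that class, and the overall rate weights each subcluster by its
    share of the dataset.
    """
    truth = np.asarray(truth)
    n = truth.size
    total = 0.0
    covered = 0
    for sc in subclustering.subclusters:
        members = np.asarray(sc.member_ids, dtype=np.int64)
        if members.size == 0:
            raise ValueError("empty subcluster")
        if members.max() >= n:
            raise ValueError("subcluster member without a ground-truth label")
        classes, counts = np.unique(truth[members], return_counts=True)
        majority = counts.max()          # lowest class id wins ties via unique order
        err = 1.0 - majority / members.size
        total += (members.size / n) * err
        covered += members.size
    if covered != n:
        raise ValueError("subclustering does not cover every labeled series")
    return total


def instruction_count(n_series: int, length: int) -> int:
    """Exact instruction count N(N-1)n²/2 of filling the full pairwise
    Euclidean distance matrix over N series of length n."""
    if n_series < 2 or length < 1:
        raise ValueError("need N >= 2 and n >= 1")
    return n_series * (n_series - 1) * length * length // 2
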