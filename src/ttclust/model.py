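"""Model/Results front end for two-step time-series clustering.

``TwoStepClustering`` is built from data (an array, DataFrame, or UCR-style
file) and holds everything fixed about a study; ``fit`` runs the pipeline for
a choice of affinity threshold and cluster count and returns a ``TTCResults``
object carrying the partition, the intermediate subclustering, the evaluation
statistics against any ground-truth labels, and a ``summary()`` table.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cast import CastParams
from .dataset import TimeSeriesDataset, load_ucr
from .kmedoids import KMedoidsParams
from .metrics import (
    EvaluationReport,
    con_entropy,
    error_rate,
    pair_counts,
    per_cluster_entropies,
    rand_index,
    reduction_factor,
)
from .pipeline import TTCRun, baseline_kmedoids, ttc_cluster

__all__ = ["TwoStepClustering", "TTCResults"]


class TwoStepClustering:
    """Two-step time-series clustering model.

    Parameters
    ----------
    data : (N, n) array of equal-length series, one per row.
    labels : optional ground-truth class ids, used only for evaluation.
    normalize : z-normalize every series before clustering (default True).
    similarity : ED-distance-to-similarity conversion: "pearson" (default;
        the correlation of z-normalized series), "minmax", or "inverse".
    prototype_normalize : "count" (literal affinity-weighted sum over member
        count) or "affinity" (weighted mean).
    """

    def __init__(
        self,
        data,
        labels: Optional[Sequence[int]] = None,
        normalize: bool = True,
        similarity: str = "pearson",
        prototype_normalize: str = "count",
    ) -> None:
        if isinstance(data, TimeSeriesDataset):
            if labels is not None:
                data = TimeSeriesDataset(data.values, labels=labels, ids=data.ids)
            self.dataset = data
        else:
            self.dataset = TimeSeriesDataset(np.asarray(data, dtype=np.float64), labels=labels)
        self.normalize = normalize
        self.similarity = similarity
        self.prototype_normalize = prototype_normalize

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: Optional[str] = None, **kwargs):
        """Build the model from a DataFrame of series rows, optionally naming
        the column that holds ground-truth class labels."""
        if label_column is not None:
            labels = df[label_column].to_numpy()
            values = df.drop(columns=[label_column]).to_numpy(dtype=float)
            return cls(values, labels=labels, **kwargs)
        return cls(df.to_numpy(dtype=float), **kwargs)

    @classmethod
    def from_ucr(cls, path, labeled: bool = True, delimiter: Optional[str] = None, **kwargs):
        """Build the model from a UCR-style delimited file."""
        return cls(load_ucr(path, labeled=labeled, delimiter=delimiter), **kwargs)

    def fit(
        self,
        k: int,
        alpha: float = 0.8,
        target_subclusters: Optional[int] = None,
        max_sweeps: int = 100,
        km_init: str = "pam-build",
        seed: Optional[int] = None,
        max_iter: int = 300,
        dtw_normalize_by_path: bool = False,
        dtw_window: Optional[int] = None,
    ) -> "TTCResults":
        """Run the two-step pipeline and return a results object.

        ``alpha`` is the affinity threshold of the subclustering step;
        ``target_subclusters`` instead searches for the threshold giving
        approximately that many subclusters. ``k`` is the final number of
        clusters (set it to the known class count when evaluating against
        labels).
        """
        run = ttc_cluster(
            self.dataset,
            CastParams(alpha=alpha, max_sweeps=max_sweeps),
            KMedoidsParams(k=k, init=km_init, seed=seed, max_iter=max_iter),
            normalize=self.normalize,
            similarity=self.similarity,
            prototype_normalize=self.prototype_normalize,
            dtw_normalize_by_path=dtw_normalize_by_path,
            dtw_window=dtw_window,
            target_subclusters=target_subclusters,
        )
        return TTCResults(self, run)

    def fit_baseline(
        self,
        k: int,
        representation: str = "raw-ed",
        paa_ratios: Sequence[int] = (4, 6, 8),
        seed: Optional[int] = None,
        restarts: int = 0,
    ) -> "BaselineResults":
        """Fit the conventional k-medoids baseline (raw ED or PAA-reduced)."""
        results = baseline_kmedoids(
            self.dataset,
            KMedoidsParams(k=k, seed=seed),
            representation=representation,
            paa_ratios=paa_ratios,
            normalize=self.normalize,
            restarts=restarts,
        )
        return BaselineResults(self, representation, list(paa_ratios), results)


class TTCResults:
    """Fitted two-step clustering: final partition plus diagnostics."""

    def __init__(self, model: TwoStepClustering, run: TTCRun) -> None:
        self.model = model
        self.run = run
        self.assignment = run.assignment
        self.k = run.k
        self.m = run.subclustering.m
        self.alpha = run.alpha
        self.medoid_subclusters = run.kmedoids.medoids

    def evaluate(self) -> EvaluationReport:
        """Score the fit against the model's ground-truth labels."""
        labels = self.model.dataset.labels
        if labels is None:
            raise ValueError("the model has no ground-truth labels to evaluate against")
        return EvaluationReport(
            rand_index=rand_index(self.assignment, labels),
            con_entropy=con_entropy(self.assignment, labels),
            per_cluster_entropy=per_cluster_entropies(self.assignment, labels),
            pair_counts=pair_counts(self.assignment, labels),
            reduction_factor=reduction_factor(self.m, self.model.dataset.n_series),
            error_rate=error_rate(self.run.subclustering, labels),
        )

    def summary(self) -> str:
        """Human-readable summary table of the fit."""
        ds = self.model.dataset
        lines = [
            "Two-step time-series clustering results",
            "=" * 46,
            f"{'series (N)':<28}{ds.n_series:>18}",
            f"{'series length (n)':<28}{ds.length:>18}",
            f"{'affinity threshold (alpha)':<28}{self.alpha:>18.4f}",
            f"{'subclusters (M)':<28}{self.m:>18}",
            f"{'reduction factor (M/N)':<28}{self.m / ds.n_series:>18.4f}",
            f"{'final clusters (k)':<28}{self.k:>18}",
            f"{'k-medoids cost':<28}{self.run.kmedoids.cost:>18.4f}",
        ]
        if ds.labels is not None:
            rep = self.evaluate()
            lines += [
                "-" * 46,
                f"{'Rand index':<28}{rep.rand_index:>18.4f}",
                f"{'ConEntropy':<28}{rep.con_entropy:>18.4f}",
                f"{'reduction error rate':<28}{rep.error_rate:>18.4f}",
            ]
        lines.append("=" * 46)
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serializable report: assignment, M, medoids, statistics."""
        out = {
            "assignment": self.assignment.tolist(),
            "k": self.k,
            "m": self.m,
            "alpha": self.alpha,
            "medoid_subclusters": self.medoid_subclusters.tolist(),
        }
        if self.model.dataset.labels is not None:
            out["evaluation"] = _jsonable(self.evaluate().as_dict())
        return out

    def save_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_report(), fh, indent=2)


class BaselineResults:
    """Conventional k-medoids baseline fit (one result per representation)."""

    def __init__(self, model, representation, paa_ratios, results) -> None:
        self.model = model
        self.representation = representation
        self.paa_ratios = paa_ratios
        self.results = results

    @property
    def assignments(self):
        return [r.assignment for r in self.results]

    def rand_index(self) -> float:
        """Rand index against the model labels; for the PAA representation
        this is the mean over the compression ratios."""
        labels = self.model.dataset.labels
        if labels is None:
            raise ValueError("the model has no ground-truth labels to evaluate against")
        return float(np.mean([rand_index(a, labels) for a in self.assignments]))

    def con_entropy(self) -> float:
        labels = self.model.dataset.labels
        if labels is None:
            raise ValueError("the model has no ground-truth labels to evaluate against")
        return float(np.mean([con_entropy(a, labels) for a in self.assignments]))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
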