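"""Distance kernels and matrices: Euclidean, DTW, similarity conversion, PAA.

Euclidean distance captures similarity *in time* (pointwise closeness) and
drives the affinity subclustering step; dynamic time warping (DTW) captures
similarity *in shape* (common trends regardless of phase) and is reserved for
the small prototype-to-prototype matrix of the merge step. The DTW inner loop
is JIT-compiled with numba so full prototype matrices stay cheap.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from numba import njit
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "euclidean_distance",
    "dtw_distance",
    "pairwise_matrix",
    "distance_to_similarity",
    "paa_transform",
]


def euclidean_distance(x: np.ndarray, y: np.ndarray, squared: bool = False) -> float:
    """Euclidean distance between two equal-length series.

    ``squared=True`` skips the square root; the square root is monotone, so
    rankings (all that clustering consumes) are unchanged.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"unequal lengths {x.shape} vs {y.shape}")
    s = float(np.sum((x - y) ** 2))
    return s if squared else float(np.sqrt(s))


@njit(cache=True)
def _dtw_dp(x, y, window):  # pragma: no cover - exercised via dtw_distance
    # rolling two-row DP: O(m) memory, no per-call matrix allocation
    n = x.shape[0]
    m = y.shape[0]
    inf = np.inf
    prev_c = np.empty(m + 1)
    cur_c = np.empty(m + 1)
    prev_s = np.zeros(m + 1, dtype=np.int64)
    cur_s = np.zeros(m + 1, dtype=np.int64)
    for j in range(1, m + 1):
        prev_c[j] = inf
    prev_c[0] = 0.0
    for i in range(1, n + 1):
        for j in range(m + 1):
            cur_c[j] = inf
        if window < 0:
            j_lo, j_hi = 1, m
        else:
            j_lo = max(1, i - window)
            j_hi = min(m, i + window)
        xi = x[i - 1]
        for j in range(j_lo, j_hi + 1):
            c = abs(xi - y[j - 1])
            # tie-break prefers the diagonal move, then the vertical
            best = prev_c[j - 1]
            bs = prev_s[j - 1]
            if prev_c[j] < best:
                best = prev_c[j]
                bs = prev_s[j]
            if cur_c[j - 1] < best:
                best = cur_c[j - 1]
                bs = cur_s[j - 1]
            cur_c[j] = c + best
            cur_s[j] = bs + 1
        prev_c, cur_c = cur_c, prev_c
        prev_s, cur_s = cur_s, prev_s
    return prev_c[m], prev_s[m]


def dtw_distance(
    x: np.ndarray,
    y: np.ndarray,
    normalize_by_path: bool = False,
    window: Optional[int] = None,
) -> float:
    """Dynamic time warping distance between two equal-length series.

    Minimal cumulative cost of a monotone warping path from (1,1) to (n,n)
    in the local-cost lattice ``Z[i,j] = |x_i - y_j|``, with the moves
    (i+1,j), (i,j+1), (i+1,j+1). ``normalize_by_path=True`` divides by the
    number of lattice points on the optimal path. ``window`` restricts the
    path to a Sakoe-Chiba band ``|i-j| <= window`` (a speed option; the
    default is unconstrained).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty series")
    w = -1 if window is None else int(window)
    if w >= 0 and w < abs(x.shape[0] - y.shape[0]):
        raise ValueError("window too narrow to reach the (n, n) boundary")
    total, nsteps = _dtw_dp(x, y, w)
    if normalize_by_path:
        # nsteps counts the lattice points on the optimal path
        return float(total) / float(nsteps)
    return float(total)


@njit(cache=True, fastmath=True)
def _dtw_dp_sum(x, y, window):  # pragma: no cover
    # cumulative-cost-only kernel (no path-length tracking): the hot path
    n = x.shape[0]
    m = y.shape[0]
    inf = np.inf
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    for j in range(1, m + 1):
        prev[j] = inf
    prev[0] = 0.0
    for i in range(1, n + 1):
        for j in range(m + 1):
            cur[j] = inf
        if window < 0:
            j_lo, j_hi = 1, m
        else:
            j_lo = max(1, i - window)
            j_hi = min(m, i + window)
        xi = x[i - 1]
        for j in range(j_lo, j_hi + 1):
            c = xi - y[j - 1]
            if c < 0.0:
                c = -c
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = c + best
        prev, cur = cur, prev
    return prev[m]


@njit(cache=True)
def _dtw_pairwise(data, window, normalize):  # pragma: no cover
    m = data.shape[0]
    out = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            if normalize:
                total, nsteps = _dtw_dp(data[a], data[b], window)
                d = total / nsteps
            else:
                d = _dtw_dp_sum(data[a], data[b], window)
            out[a, b] = d
            out[b, a] = d
    return out


def pairwise_matrix(
    values: np.ndarray,
    metric: str = "ed",
    normalize_by_path: bool = False,
    window: Optional[int] = None,
) -> np.ndarray:
    """Symmetric pairwise distance matrix over the rows of ``values``.

    metric : {"ed", "dtw"}
        Euclidean distance or dynamic time warping. Only the upper triangle
        is computed and mirrored.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError("expected an (N, n) matrix")
    if values.shape[0] == 1:
        return np.zeros((1, 1))
    if metric == "ed":
        return squareform(pdist(values, metric="euclidean"))
    if metric == "dtw":
        w = -1 if window is None else int(window)
        return _dtw_pairwise(np.ascontiguousarray(values), w, normalize_by_path)
    raise ValueError(f"unknown metric {metric!r}")


def distance_to_similarity(
    dist: np.ndarray, method: str = "pearson", length: Optional[int] = None
) -> np.ndarray:
    """Convert a distance matrix to a similarity matrix with entries in [0,1].

    The affinity threshold of the subclustering step lives on a [0, 1] scale,
    so Euclidean distances are rescaled. Three conversions are provided:

    - ``pearson`` (default; requires ``length``): ``1 - D²/(2n)`` clipped to
      [0, 1]. For z-normalized series of length n this is exactly the Pearson
      correlation between the two series (negative correlations clip to 0),
      the similarity scale the affinity-search technique inherited from its
      gene-expression origins; thresholds around 0.7-0.9 then mean "strongly
      correlated in time", independent of the dataset at hand.
    - ``minmax``: ``1 - D/max(D)`` (all-ones if ``max(D) = 0``), a purely
      dataset-relative scale.
    - ``inverse``: ``1/(1 + D)``.

    The diagonal is exactly 1 in every case.
    """
    dist = np.asarray(dist, dtype=np.float64)
    if method == "pearson":
        if length is None:
            raise ValueError("the pearson conversion needs the series length")
        sim = np.clip(1.0 - dist**2 / (2.0 * length), 0.0, 1.0)
    elif method == "minmax":
        dmax = dist.max()
        sim = np.ones_like(dist) if dmax == 0 else 1.0 - dist / dmax
    elif method == "inverse":
        sim = 1.0 / (1.0 + dist)
    else:
        raise ValueError(f"unknown similarity conversion {method!r}")
    np.fill_diagonal(sim, 1.0)
    return sim


def paa_transform(values: np.ndarray, compression_ratio: int) -> np.ndarray:
    """Piecewise aggregate approximation: replace consecutive frames of
    ``compression_ratio`` points by their means (the last frame may be short).

    Works on a single series or on each row of a matrix; a series of length n
    shrinks to ceil(n / compression_ratio).
    """
    values = np.asarray(values, dtype=np.float64)
    single = values.ndim == 1
    mat = values[None, :] if single else values
    n = mat.shape[1]
    r = int(compression_ratio)
    if r < 1:
        raise ValueError("compression_ratio must be >= 1")
    if r > n:
        raise ValueError(f"compression_ratio {r} exceeds series length {n}")
    edges = np.arange(0, n, r)
    out = np.add.reduceat(mat, edges, axis=1)
    sizes = np.diff(np.append(edges, n))
    out = out / sizes
    return out[0] if single else out
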