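# ttclust — two-step time-series clustering

Clustering time series by *shape* (common trends, regardless of when they
occur) needs an elastic distance such as dynamic time warping (DTW), but
filling a full N×N DTW matrix is quadratic in both the number of series and
their length — for N = 1000 series of length n = 152, the Euclidean matrix
alone already costs N(N−1)n²/2 ≈ 1.15×10¹⁰ elementary operations, and DTW is
n-fold worse. `ttclust` implements a two-step strategy that sidesteps this:

1. **Reduction** — z-normalize every series, group series that are similar
   *in time* (pointwise, by Euclidean distance converted to a [0,1]
   similarity) into *subclusters* with the cluster affinity search technique
   (CAST): clusters grow by admitting the series whose mean similarity
   (*affinity*) to the current members clears a threshold α, and shed members
   whose affinity falls below it. Each of the M ≪ N subclusters is condensed
   into a single affinity-weighted *prototype*
   `r = Σ_y a(F_y)·F_y / |SC|`.
2. **Merging** — compute the M×M DTW distance matrix over the prototypes
   only, partition the prototypes with k-medoids (PAM: greedy BUILD
   initialization + best-improvement SWAP refinement), and let every series
   inherit the final cluster of its subcluster's prototype.

The expensive shape comparison therefore touches only M prototypes, with the
reduction factor M/N controlled by α. The package also ships the standard
evaluation statistics (Rand index, normalized cluster entropy / ConEntropy,
reduction factor, majority-class error rate of the reduction step), the
conventional k-medoids baselines on raw-ED and PAA-reduced series, and a
seeded Cylinder-Bell-Funnel (CBF) generator so every experiment runs without
external data. Intended users: anyone clustering equal-length numeric time
series — gene-expression time courses, physiological signals, sensor traces.

## Worked example

```python
from ttclust import CbfConfig, TwoStepClustering, generate_cbf

data = generate_cbf(CbfConfig(counts=(100, 100, 100), seed=1))
model = TwoStepClustering(data)          # labels travel with the dataset
result = model.fit(k=3, alpha=0.8)
print(result.summary())
```

```
Two-step time-series clustering results
==============================================
series (N)                                 300
series length (n)                          128
affinity threshold (alpha)              0.8000
subclusters (M)                            180
reduction factor (M/N)                  0.6000
final clusters (k)                           3
k-medoids cost                       6743.5449
----------------------------------------------
Rand index                              0.9331
ConEntropy                              0.8302
reduction error rate                    0.0000
==============================================
```

Reading: the 300 series were condensed to M = 180 subclusters (a 40%
data-size reduction) that are perfectly class-pure at this threshold
(reduction error rate 0); DTW k-medoids over the 180 prototypes then
recovers the three CBF classes with Rand index 0.933 (fraction of series
pairs on which the clustering agrees with the ground truth) and ConEntropy
0.83 (1 = perfectly pure clusters). The conventional baseline on the same
data, `model.fit_baseline(k=3).rand_index()`, scores 0.639 — the pointwise
Euclidean metric cannot absorb the random event onsets that DTW warps away.

The same pipeline is available from the shell:

```sh
ttclust simulate --classes 100,100,100 --seed 1 --out cbf.tsv
ttclust cluster cbf.tsv --k 3 --alpha 0.8 --baseline ed --out report.json
ttclust evaluate report.json cbf.tsv
```

Input files are UCR-style delimited text: one series per row, optional
integer class label in the first column.

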