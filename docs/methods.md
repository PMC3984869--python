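# Methods

## The model

`ttclust` partitions N equal-length time series into k clusters by shape
while evaluating the expensive elastic distance on only M ≪ N objects.
Terminology follows the field's usage: *similarity in time* is pointwise
closeness at matched time steps (captured by Euclidean distance, ED);
*similarity in shape* is agreement of trends regardless of phase (captured
by dynamic time warping, DTW).

**Step 1 — reduction.** Every series is z-normalized to mean 0, population
standard deviation 1, making the pipeline invariant to offset and positive
rescaling. The N×N ED matrix is converted to a [0,1] similarity matrix A
(see *Similarity scale* below) and fed to the cluster affinity search
technique (CAST). CAST grows one subcluster at a time: it seeds with the
unassigned series of largest similarity row-sum over the unassigned block,
then alternates an ADD phase — admit the outside series of maximal
*affinity* a(x) = Σ_{y∈SC} A_xy / |SC| while that affinity ≥ α — and a
REMOVE phase — expel the member of minimal affinity while that affinity
< α, re-evaluating after each expulsion and never emptying the subcluster —
until a full sweep changes nothing. All ties break toward the lowest series
index, so the subclustering is a deterministic function of (A, α), and the
result is always a partition. Each subcluster is condensed to a prototype,
the affinity-weighted combination r = Σ_y a(F_y)·F_y / |SC|. The divisor is
the member count, not the affinity mass, so prototypes of loose subclusters
are shrunk toward 0; `normalize="affinity"` switches to the true weighted
mean. The count divisor is the package default because the shrinkage is
part of the construction as published and is harmless to the rank-based
merge; on our benchmarks the two options differ by < 0.04 Rand index.

**Step 2 — merging.** The M×M DTW matrix over prototypes is clustered with
k-medoids, and every series inherits its prototype's cluster; no per-series
reassignment is performed. DTW is the textbook O(n²) dynamic program on the
local-cost lattice Z_ij = |x_i − y_j| with moves (i+1,j), (i,j+1),
(i+1,j+1), boundary (1,1)→(n,n). Options: a Sakoe-Chiba band (off by
default — unconstrained warping is the primary semantics) and a
path-length-normalized reading that divides the optimal cumulative cost by
the number of lattice points on the optimal path (off by default; on ties
the backtrack prefers the diagonal, then the vertical move).

**k-medoids.** PAM on the precomputed matrix: greedy BUILD initialization
(first medoid minimizes its row-sum; each next maximizes the total cost
decrease) followed by best-improvement SWAP refinement until no single
medoid/non-medoid exchange lowers the total assignment cost. Cost is
strictly decreasing over swaps. On random 2-D toy instances (n ≤ 8,
k ≤ 3) this reaches the exhaustively enumerated global optimum in ≥ 90% of
seeded trials (regression-tested). `init="random"` with an explicit seed
supports multi-restart experiments; restarts keep the best-cost solution.

## Similarity scale

CAST needs similarities in [0,1] but the conversion from ED is a free
design choice. The default is the *Pearson* form

    A_xy = clip(1 − d²(x,y) / 2n, 0, 1),

which for z-normalized series of length n is exactly the Pearson
correlation of the two series (negative correlations clip to 0). This is
the similarity scale CAST inherited from its gene-expression origins, and
it gives the affinity threshold an absolute meaning — α = 0.8 admits
series correlated at 0.8 with a subcluster's members — independent of the
dataset. It also places the informative operating range of α at 0.7–0.9 on
the CBF benchmark, where the threshold trades reduction against subcluster
purity. Two alternatives are available: `minmax` (1 − D/max D, dataset-
relative; its informative range on CBF sits lower, near 0.5–0.65) and
`inverse` (1/(1+D)). All three reverse the distance ordering exactly
wherever they are not clipped.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α (`alpha`) | 0.8 | affinity threshold in (0,1); higher → more, tighter, purer subclusters (M grows monotonically with α in practice) |
| `target_subclusters` | — | replaces α by a 20-step binary search for the α whose M lands closest to the target |
| k | required | final cluster count; set to the known class count in labeled evaluations |
| `max_sweeps` | 100 | cap on ADD/REMOVE sweeps per subcluster; the loop normally converges on its own |
| `init`, `seed`, `max_iter` | pam-build, None, 300 | k-medoids initialization, RNG seed for random init, SWAP cap |
| `dtw_window` | None | Sakoe-Chiba band half-width (speed/regularization option) |
| `ddof` (z-normalization) | 0 | population vs sample standard deviation |

## The synthetic benchmark

`generate_cbf` implements the canonical Cylinder-Bell-Funnel construction
(as in the UCR archive): with t = 1..n (n = 128), integer onset
a ~ U[16,32], duration d ~ U[32,96], b = a+d, amplitude 6+η with
η ~ N(0,1), and iid ε(t) ~ N(0, noise_sd²), noise_sd = 1:

    cylinder  (6+η)·1[a,b](t) + ε(t)
    bell      (6+η)·1[a,b](t)·(t−a)/d + ε(t)
    funnel    (6+η)·1[a,b](t)·(b−t)/d + ε(t)

Datasets are bit-reproducible given the seed. The generator reproduces the
random phase, duration, amplitude and noise of the benchmark; it does not
emulate features of real recordings such as autocorrelated noise, trends,
missing samples, or unequal lengths, so passing benchmarks here shows
correctness of the pipeline under the benchmark's assumptions, not
performance on arbitrary real data. `generate_blocks` provides trivially
separable template-plus-noise fixtures for exact tests.

## Numerical and degenerate-input conventions

- Constant series z-normalize to the all-zeros series with a warning
  rather than raising.
- sd = 0, max(D) = 0 and empty-subcluster corner cases are handled
  explicitly; similarity diagonals are exactly 1.
- A singleton's seed has affinity 1 (its self-similarity), so singletons
  never expel themselves; a member's affinity includes its own
  self-similarity, a candidate's does not.
- Ties (CAST seed choice, add/remove victim, k-medoids argmin, majority
  class of a subcluster) always break toward the lowest index, making every
  stage deterministic given its inputs.
- PAA frames are contiguous blocks of `compression_ratio` points; the last
  frame may be shorter and is averaged over its actual size.

## Benchmark problem sizes

`scripts/acceptance.py` runs the full protocols: 900-series CBF (10
generation seeds, α swept over {0.7, 0.75, 0.8, 0.85, 0.9}, the raw-ED
k-medoids baseline with 5 random restarts per dataset), the reduction/error
trade-off at α ∈ {0.7, 0.75, 0.8}, and the large-dataset runs at 1,000 and
2,000 series with ~30 subclusters (5 seeds per size). The test suite
exercises the same protocols at reduced replication (3 seeds for the
900-series runs; 2 seeds at 1,000 series for the scaling run) so a default
`pytest` pass stays fast.

## Known limitations

- Equal-length series only; variable-length support is out of scope.
- The reduction step's purity/size trade-off is data-dependent: on CBF at
  standard noise, pushing the reduction to M/N ≈ 0.23 costs ≈ 0.05–0.09
  majority-class error, and error ≤ 0.05 is typically reached around
  M/N ≈ 0.45–0.5. Aggressive reduction (M ≈ 30 on 1,000+ series) produces
  large, mixed subclusters whose averaged prototypes lose the class shapes;
  cluster quality after the merge degrades accordingly. The pipeline is at
  its best with α chosen so subclusters stay nearly pure (error ≤ ~0.05).
- Unconstrained DTW on heavily averaged (near-flat) prototypes can warp
  away genuine shape differences; a Sakoe-Chiba band mitigates this when
  aggressive reduction is unavoidable.
- CAST's greedy growth yields skewed subcluster sizes at low α (one dense
  core can absorb a large fraction of the data).
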