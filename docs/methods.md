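# Methods

## The clustering-tendency index

The package scores an *n* × *d* embedding by how strongly its points
aggregate.  Three ingredients:

**Average scale.**  *M* is the 25th percentile (linear interpolation) of
the *n*(*n*−1)/2 unordered pairwise Euclidean distances; the diagonal
zeros of the distance matrix are not pairs and are excluded.  The scale is
*s* = *M*/log₁₀ *n*: the wider the cloud, the looser the notion of
"close"; the more points, the stricter.  If *M* = 0 (at least three
quarters of all pairs coincide) the index is undefined and the package
raises a degenerate-data error rather than substituting an epsilon —
silent substitution would mask duplicated-cell artifacts.  *n* = 1 is
rejected for the same reason (log₁₀ 1 = 0).

**Greedy aggregation.**  One pass works as follows: a starting point is
drawn uniformly at random and forms the active cluster.  Repeatedly, among
the *unassigned* points, the point nearest to the active cluster's
geometric center (the arithmetic mean of its members) is located; if its
distance to the center is strictly below *s* it is absorbed and the center
updated exactly, otherwise it founds a new cluster which becomes the
active one.  Closed clusters are never revisited and points are never
reassigned.  Equidistant candidates resolve to the lowest point index, so
a pass is fully determined by its starting point.  A distance exactly
equal to *s* opens a new cluster (the comparison is strict).

**Index.**  After all points are assigned, each cluster's radius is the
mean distance of its members to the cluster's *final* center; *R* is the
unweighted mean of the *K* radii (singletons contribute 0), and the pass
returns 1 − *R*/*s*.  The reported score is the mean over `repeats`
passes (default 100), each drawing only its starting point from an
independent substream spawned from the user seed; everything else is
deterministic, so a fixed (input, repeats, seed) triple reproduces the
score bit-for-bit.  The index is ≤ 1 always, with equality exactly when
every radius is 0; it is *not* clipped below — if center drift pushes
*R* above *s* the negative value is reported as-is, since only the
ordering across preprocessing paths matters.

Properties worth knowing:

* **Similarity invariance.**  Distances, *M* and *R* transform together
  under translation, rotation and positive uniform scaling, so the score
  is invariant with a shared seed.  In floating point the invariance is
  exact (bit-identical) for scaling by powers of two and holds to ~1e−9
  relative error under general rotations/translations.
* **Saturating contraction response.**  For points around fixed centers,
  shrinking the within-center spread raises the index only while
  within-cluster pairs make up less than a quarter of all pairs.  Beyond
  that the lower-quartile distance itself tracks the shrinking spread and
  the (scale-invariant) index plateaus.  The monotonicity test therefore
  uses five equal clusters (within-pair fraction ≈ 0.20), where the
  quartile is pinned by the fixed between-center geometry.
* **Density without structure scores high.**  Any embedding with one
  dense core plus scattered outliers earns a high index: the core forms
  one cluster and each outlier a singleton of radius 0, deflating the
  unweighted mean radius.  See *Limitations*.

## Preprocessing registry

Candidate paths are the Cartesian product of named normalizations
(matrix → matrix) and reductions (matrix → embedding).  Built-ins:

| name | transform | default parameters |
|---|---|---|
| `identity` | raw counts passthrough (negative control) | — |
| `log` | log(*x* + 1), natural log | pseudocount 1 |
| `libsize` | per-cell total rescaled to 10⁴, then log1p | target_sum 10⁴ |
| `scale` | per-gene z-score (sample sd, ddof = 1; constant genes → 0 with a warning) | — |
| `tmm` | trimmed-mean-of-M-values effective library scaling, then log1p | trim 0.30 (M), 0.05 (A) |
| `pca` | top-*d* principal axes, sign-fixed so each axis's largest loading is positive | *d* = 2 |
| `sammon` | Sammon mapping, PCA-initialized descent | *d* = 2, 200 iterations |
| `tsne` | seeded t-SNE (inputs above 50 features are PCA-reduced to 50 first, the standard pipeline) | *d* = 2, perplexity 30 |

The scaling-factor normalizations (`libsize`, `tmm`) hand **log-scale**
expression to the reduction because that is what their real counterparts
do (log-CPM after TMM factors; LogNormalize-style library scaling); the
primitive operations (`normalize_library_size`, `normalize_log`,
`normalize_scale`, `tmm_factors`) remain pure and individually usable.
TMM selects as reference the cell whose upper-quartile expression fraction
is closest to the cross-cell mean, forms M/A values over genes positive in
both cells, discards the extreme 30%/5% quantile tails of M/A, takes the
inverse-variance-weighted mean of the kept M values, and renormalizes
factors to geometric mean 1.  Plug-ins register through
`MethodRegistry.add_normalization` / `add_reduction`; registered
transforms must be pure functions of their input plus the explicit seed
they receive.

Per-combination sub-seeds are derived from the top-level seed and the
combo name via SHA-256, so adding or removing combos never perturbs the
others and a sweep reproduces an independent loop over the public
per-combo functions exactly.  Paths whose preprocessing raises are
recorded with their failure reason instead of aborting the sweep.

### Sammon mapping numerics

Stress E = (Σ d\*ᵢⱼ)⁻¹ Σ (d\*ᵢⱼ − dᵢⱼ)²/d\*ᵢⱼ over *i* < *j* is minimized
by normalized-gradient steps from the (deterministic) PCA projection with
backtracking halving: a step is accepted only if it lowers the stress, so
accepted stress is non-increasing; the step doubles (capped at 1) after
acceptance.  Descent stops at relative improvement below 1e−9, a zero
gradient, 30 failed halvings, or 200 accepted steps — the last case
returns the best-so-far embedding with a warning.  Duplicate input rows
make the stress undefined and are rejected with guidance.  Embedded
distances are floored at 1e−12 in the gradient to survive transient
coincidences.

## Selection and evaluation

`score_all` scores every combo; `select_best` is a pure argmax of the mean
index with exact ties broken lexicographically by (normalization,
reduction) name.  Downstream clustering offers seeded k-means (10
restarts) and Ward-linkage agglomeration cut at *k*; *k* must be supplied
(taken from the truth labels in the CLI's evaluate mode).  Agreement with
reference labels uses the Adjusted Rand Index from the contingency table,
with the degenerate identical-trivial-partition case scoring 1.
`evaluate_combos` computes each combo's embedding once, reports a tidy
(combo × clusterer) table with the index, the ARI and the selected flag,
and summarizes the selected combo's quantile rank per clusterer (upper
quantile = 75th percentile, linear interpolation).

## Synthetic data

**Shapes.**  Four 2-D generators — isotropic Gaussian (sd = spread),
square outline (side ∝ spread), hexagram outline (two overlapping
equilateral triangles, points equally spaced along the six edges), and
uniform box — with outline jitter sd fixed at 2% of the spread.  Each
shape is built in a unit frame and multiplied by the spread last, so draws
differing only in spread are exact rescalings; along the default spread
grid (4, 2, 1, 0.5) — powers of two — the index is bit-identical, which is
the sharpest possible form of "non-decreasing as data aggregate" for a
scale-invariant statistic.

**Counts.**  The planted-cluster simulator draws uniform cluster labels
for `n_cells` = 500 cells; each of the `k_clusters` = 4 clusters elevates
its own block of 100 marker genes from a background negative-binomial
mean of 0.5 to 8.0 (dispersion 0.5) among `n_genes` = 2000 genes.  Every
cell's expected expression is multiplied by a lognormal sequencing-depth
factor (σ = 0.35, mean-normalized) — the per-cell technical scaling that
library-size and TMM normalization exist to remove; a simulator without it
cannot distinguish normalizations at all.  Zeros are then injected
independently at the rate that brings the overall zero fraction to the
`dropout_target` of 0.90 (± 0.02 realized), matching the sparsity regime
of droplet scRNA-seq; if the matrix is already sparser, a warning is
issued and nothing is injected.  With these defaults the planted structure
is honest but nontrivial: the standard library-size + log + PCA + k-means
pipeline recovers the labels at ARI ≈ 0.87, raw-count PCA only at ≈ 0.4.

What the simulator does **not** emulate: gene-gene correlation, mean-
dependent dropout, batch structure, doublets, or realistic gene-mean
distributions (background genes are exchangeable).  Passing tests on it
demonstrate the pipeline's mechanics and the index's behavior on
controlled geometry, not performance on real tissue atlases.

## Problem sizes and runtime

The test suite and the acceptance script run everything at desk scale:
shape sets of 500 points, count matrices of 500 × 2000, 100 aggregation
repeats per score, a 15-combination grid, two clusterers and ten simulated
datasets for the selection benchmark — a few minutes on one CPU in total.
Distances are exact (no approximate nearest neighbors); the quadratic
memory of the distance matrix limits comfortable use to roughly 10⁴ cells.

## Limitations

The selection heuristic assumes that, among the candidate embeddings,
aggregation tracks biological signal.  On the synthetic benchmark this
fails in a specific, reproducible way: per-gene z-scoring of 90%-sparse
counts maps every zero of a gene to the same value, collapsing most cells
into one dense core whose many singleton outliers inflate the index (see
*Density without structure* above), and raw-count embeddings behave
similarly.  The index then prefers exactly the paths with the least class
structure — the acceptance suite records the selected combo reaching the
across-combo median ARI in 0 of 20 (seed × clusterer) cells under the
full default grid.  Restricting the grid to the scaling-factor/log-scale
paths (`libsize`, `log`, `tmm`) makes selection competitive (at or above
the median in most cells), but the index still cannot separate near-tied
good embeddings, and t-SNE — which deliberately equalizes cluster density
— is systematically under-scored relative to its clustering quality.
Users should treat the score as a screen among *comparable, sensibly
normalized* candidates, not as an absolute quality guarantee, and keep
degenerate controls like raw or z-scored sparse counts out of the grid
when class structure matters.
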