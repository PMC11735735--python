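# Methods

This note records the model choices, defaults and numerical conventions
behind `hashdemux`, and what the simulation-based tests do and do not
establish.

## Normalization

All four methods use the natural logarithm and preserve the shape and name
order of the input. `lognorm` and `rc` divide by the per-cell total `S_j`
and rescale by `scale_factor` (default 10⁴); a cell with `S_j = 0` cannot be
depth-normalized, so its values are set to 0 with a warning (downstream it
will be Negative-labeled) rather than raising — empty droplets do occur in
real matrices.

**Geometric means with zeros.** Tag counts contain zeros, for which a plain
geometric mean is zero or undefined. Both CLR variants therefore use the
pseudocount-1 geometric mean `G = exp(mean(ln(1 + r)))` over the row
(per tag) or column (per cell). This is the convention of the widely used
single-cell toolkit implementation of CLR tag normalization, is defined for
all inputs, and converges to the plain geometric mean when counts are large.
Consequences used by the tests: a zero count always maps to 0; each method
is strictly increasing within its row (per-tag CLR) or column (per-cell
CLR), so per-tag CLR leaves per-tag AUCPR exactly unchanged.

## SNN graph and Louvain

Neighborhoods are exact Euclidean k-nearest neighbors in the M-dimensional
normalized tag space; M is at most a few dozen, so neither PCA nor
approximate indices are warranted. Each cell is included in its own
neighborhood (sets of size k + 1), edge weights are Jaccard overlaps
`|A∩B| / |A∪B|`, and edges with weight ≤ 1/15 are pruned — both conventions
follow common SNN implementations and are exposed as parameters. Louvain
(igraph `community_multilevel`) maximizes resolution-scaled modularity
`Q = Σ_c [e_c/m − γ(d_c/2m)²]`; the RNG is seeded per call, so a fixed seed
gives a reproducible partition. An edgeless graph degenerates to one cluster
per cell, which the labeling stage handles (singleton clusters yield no
marker test and become Negative).

The ensemble's default resolutions (1–4) deliberately over-cluster: each
tag's cells may split into several clusters, all of which then receive the
same marker label. Over-clustering is therefore benign for labeling but
makes the adjusted Rand index a misleading measure of cluster/tag alignment;
the tests check ARI at a granularity-matched resolution and cluster purity
at the working resolutions.

## Marker calling and calibration

For every (cluster, tag) pair a two-sided one-vs-rest Wilcoxon rank-sum test
(asymptotic, tie-corrected) is run on normalized values. A marker must be

1. expressed in all cells of the cluster — evaluated as normalized value
   > 0, which coincides with raw count > 0 for all four normalizations;
2. significant after Bonferroni correction across all (cluster, tag) tests
   of the pass (p_adj < .05; Benjamini–Hochberg available via `p_adjust`);
3. above the logFC threshold, where
   `logFC = ln[(mean_c expm1(n) + 1) / (mean_rest expm1(n) + 1)]`,
   the fold change of de-normalized means with pseudocount 1 — the marker
   convention of the standard single-cell toolkit.

The threshold is calibrated over the grid {0.1, 0.2, …, 2.0}: the rank-sum
statistics do not depend on the threshold, so they are computed once and
re-filtered per candidate. The candidate minimizing |achieved − expected
doublet rate| wins; exact ties go to the smallest threshold (the least
stringent filter consistent with the target). The achieved rate's
denominator is all cells, including Negatives.

**Expected doublet rate.** The automatic estimate
`8×10⁻⁶ · n_cells · (T−1)/T` models droplet co-encapsulation in a standard
10x 3' v3.1 run. It describes droplet loading of a *real* experiment; for
simulated data whose generating doublet rate is known (10% here), that known
rate is the scientifically correct target and is what the recovery tests
pass explicitly. Calibrating a 10%-doublet simulation against the 3.2%
loading estimate would force roughly two thirds of doublet clusters to be
relabeled as singlets by construction — a property of the mismatch between
the loading model and the simulator's stated world, not of the algorithm.

**Majority vote.** Ties are resolved Negative > Doublet > tags
(alphabetical): an ambiguous cell should not be forced into a sample.
Per-run seeds are `base_seed + run_index`; a failing run is dropped with a
warning and shrinks the confidence denominator.

## Simulator

The generator emulates a pooled hashing experiment: per-cell signal is a
uniform integer in [10, 1000] for each own tag (doublets draw twice,
independently, for a uniformly chosen unordered pair of distinct tags);
exactly `round(rate · total)` cells are doublets, spread evenly across the
initial tag blocks. Two noise layers follow:

* **cell-bound contamination** — `round(f/(1−f) · signal)` extra reads per
  cell, multinomially split over non-own tags proportionally to ambient
  levels, so contamination is exactly the fraction `f` of bound reads in
  expectation;
* **ambient contamination** — per (tag, cell) Poisson counts with tag level
  λ_i; one tag pinned at `ambient_max`, the rest log-uniform in
  [`ambient_min`, `ambient_max`]. `ambient_min` defaults to 1 read (no
  published value exists; 1 keeps the log-uniform draw well defined and the
  levels positive). Poisson is the simplest count-noise model consistent
  with a per-tag ambient *level*; the upstream simulator's exact internals
  are not public, so this is a modeling choice.

The benchmark grids: the noise grid crosses cell-bound fractions
{2%, 5%, 14%, 37%} with ambient maxima {100, 300, …, 1900} (40 combinations,
3 replicates by default → 120 datasets; 5 tags × 1000 cells, 10% doublets);
the scalability grid crosses {5, 10, 20, 40} tags with {100, 200, 400, 800}
cells per tag at low noise.

What the simulator does **not** reproduce: empty droplets, RNA expression,
batch structure, tag-specific antibody efficiency, or over-dispersed
(negative-binomial) ambient noise. A green recovery test therefore shows the
workflow solves the stated noise model at desk scale, not that it matches
any particular real dataset.

## Evaluation

* **F-score**: per-tag F1 of the one-vs-rest prediction, macro-averaged over
  tags present in the truth. Doublet and Negative are not averaged classes,
  but calling a true-tag cell Doublet/Negative costs recall and calling a
  true doublet/negative by a tag costs precision.
* **Doublet misclassification**: fraction of true doublets assigned to a tag
  (Doublet or Negative calls are not singlet errors); 0 with a warning when
  the truth has no doublets.
* **AUCPR separability**: ground-truth doublets excluded; positives = cells
  truly carrying the tag; operating points at every distinct score value
  with all ties entering together ("count larger than threshold"). Area:
  the segment from recall 0 to the first attainable positive-recall point is
  a rectangle at that point's precision; subsequent segments use the
  Davis–Goadrich nonlinear interpolation, integrated in closed form. The
  final area is clipped to [0, 1] against float drift. Degenerate cases:
  perfect separation → 1; all scores tied → the positive prevalence; no
  positives (or no negatives) → missing (None), which is distinct from 0.
* **Noise statistics**: baseline expression variability is the coefficient
  of variation (sample sd, n−1) across tags of the per-tag median of
  ln(count + 1); sequencing depth variability is the ratio of the 99th to
  the 1st linear-interpolation percentile of per-cell totals (infinite with
  a warning when the 1st percentile is 0; undefined/NaN for an all-zero
  matrix).

## Known limitations

* Runtime grows with cells × ensemble size; exact kNN is quadratic-ish in
  memory for very large N (fine at desk scale, no ANN backend).
* Samples with fewer cells than k cannot form their own neighborhood and may
  merge into another cluster — a documented failure mode of the approach.
* The calibration can only reach doublet rates attainable by whole clusters,
  so its achieved rate is quantized by cluster sizes.
* RNA-based doublet rescue and comparisons against external demultiplexers
  are out of scope.
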