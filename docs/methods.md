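# Methods

## Problem setting

`labsubspace` analyses a rectangular table of per-subject baseline laboratory
values from an acute-TBI cohort: `n` subjects × `d` numeric attributes, with
optional survival-days, baseline-availability and 6-month-mortality metadata.
The scientific question is whether subject phenotypes hide in *subspaces* —
small attribute subsets — rather than in the full attribute space, and how the
three subspace-clustering families compare with full-space k-means on the same
table under the same evaluation metrics.

## Preprocessing protocol

Cohort inclusion keeps subjects who (i) survived at least `min_survival_days`
days (default 3, boundary inclusive — day 3 stays in) and (ii) have a complete
baseline panel. Missing or unparseable numeric cells never get imputed: the
row is flagged `baseline_available = False` and the inclusion filter removes
it, mirroring the "baseline labs available" criterion. Row order is preserved
throughout; all algorithms address subjects by 0-based row position in the
filtered table.

Each attribute is then independently min-max rescaled to `[0, 10]`. A constant
column maps to 0 everywhere (any constant is equally arbitrary; 0 is
reproducible). Normalization is idempotent on non-constant columns to 1e-9.
Both coagulation attributes are normalized on the same scale as the chemistry
panel — the protocol treats the panel uniformly.

Parameter grids are arithmetic sequences `start, start+step, …` inclusive of
the maximum when reached within 1e-9 (both default density grids end exactly
on their printed maxima): MinPts 8→128 step 30 (five values), ε 0.01→0.25
step 0.03 (nine values).

## Density-based family

DBSCAN conventions: the ε-neighborhood is closed (boundary included) and
contains the query point, which counts toward the MinPts core condition.
Distances default to Euclidean; Manhattan is a config option. Cluster
extraction is implemented as connected components of the core–core adjacency
graph with border points attached afterwards; this equals the textbook
density-reachability closure (the component construction *is* the merge of
chained clusters) and is independent of visiting order. A border point within
ε of cores of two clusters is assigned to the cluster whose smallest core
index is smaller — a deterministic tie rule chosen because the classical
definition leaves shared borders ambiguous.

SUBCLU searches bottom-up. Level 1 runs DBSCAN per single attribute. Level
k+1 forms candidates by the Apriori join (two k-subspaces sharing k−1
attributes) pruned by anti-monotonicity (all k-subsets must carry a cluster),
then runs **one** DBSCAN per candidate, restricted to the union of clustered
objects of the parent k-subspace with the fewest clustered objects. The union
restriction is the exactness-critical choice: every member, and every
neighborhood member of every core, of a candidate-level cluster lies within ε
of some parent core and is therefore inside the union; restricting to a
*single* parent cluster instead can strand a border point that the parent's
tie rule assigned to a sibling cluster, silently dropping a candidate cluster
below MinPts. With the union restriction the output is provably identical to
exhaustive DBSCAN over all `2^d − 1` subspaces, and the test suite asserts
this equality on randomized tables. A `max_dim` cap on subspace size is
exposed (default unlimited). SUBCLU's noise set is the objects in no cluster
of any subspace. Neighborhoods use brute-force pairwise distances — at
hundreds of subjects a spatial index would cost more than it saves.

## Cell-based family

A cube anchors at a seed object: per attribute the window is
`[x_seed − w/2, x_seed + w/2]`, shifted (not shrunk) to fit inside `[0, v]`
so every interval has exactly width `w`. Attributes are scanned in ascending
index and accepted greedily when at least `τ` of the objects already inside
the cube fall in the window — ascending order for determinism. Mining draws
`n_seeds` seeds per round (seeded RNG, without replacement from the unmined
pool), keeps the cube maximizing `|O| · (1/β)^{|S|}` (the DOC-lineage quality;
β default 0.25), emits it, removes its objects, and repeats until no cube
reaches `τ`. Removal gives pairwise-disjoint clusters.

Defaults `w = 1.0` normalized units and `τ = ⌈0.05·n⌉` are declared package
conventions. Note the interaction that makes `τ` matter: a width-1.0 window
covers ~10% of a uniform attribute, so with `τ` below ~10% of the candidate
pool the greedy admits uninformative attributes. The *recoverable regime* used
in the recovery tests therefore sets `τ` near half the planted cluster size
(τ = 30 for sizes 60), which rejects uniform windows while keeping planted
ones.

## Clustering-oriented family

PROCLUS-style: sample `A = a·k` objects (default a = 30), farthest-first down
to `B = b·k` candidates (default b = 3), start from the first k. Localities
are full-space Voronoi cells of the medoids. Dimension selection standardizes
per-attribute mean absolute deviations within each locality (z-score across
attributes, sample SD) and picks the `k·l` globally smallest, each medoid
keeping at least two attributes — which forces `l ≥ 2`, validated at
construction. Assignment minimizes segmental distance (projected Manhattan
divided by `|S|`, making different-sized subspaces comparable); ties go to the
lower medoid index. The hill-climb swaps the smallest cluster's medoid for a
random unused pool candidate, keeps the best objective (unweighted mean over
clusters of mean member segmental distance), and stops after `max_iter` = 20
consecutive non-improving swaps. Outlier handling is off by default (coverage
1); when enabled, an object farther (segmentally) from its medoid than any of
that medoid's locality members becomes noise. Recovery tests run it off, on
tables where all objects are planted, because a full-coverage partitioner
cannot match planted memberships in the presence of background objects.

k-means is hand-rolled Lloyd iteration (seeded random initial centers, best of
`n_restarts` = 10 by within-cluster sum of squares, empty clusters re-seeded
at the worst-fit point) so the non-increase of the objective can be asserted
at every iteration; scikit-learn's KMeans serves as the independent
cross-check of the attained optimum in the tests, never as the implementation.

## Evaluation metrics

- **F1**: per hidden cluster, take the found cluster with maximum object
  overlap (overlap ties broken by higher F1, then deterministic order);
  report the unweighted mean of the per-hidden F1 values (macro averaging, the
  convention of the subspace-clustering benchmark literature).
- **Entropy**: size-weighted mean over clusters of the Shannon entropy of
  within-cluster label proportions, normalized by `log2(#labels)` to `[0, 1]`;
  objects in several clusters count once per cluster; undefined (reported
  missing, never 0) when there are no clusters.
- **Coverage**: `|∪ O_C| / n`.
- **Average dimensionality**: unweighted mean of `|S|` over clusters.
- **Accuracy**: each cluster maps to its majority label (within-cluster ties →
  global majority); each object is predicted by majority vote over its
  containing clusters' mapped labels (vote ties and uncovered objects → global
  majority); global-majority ties resolve to the smallest label. Accuracy
  dominates the majority-class prevalence whenever clusters are disjoint; with
  overlapping clusters the vote can dip below it, so the fuzz suite asserts
  the bound on disjoint clusterings and the `[0, 1]` range everywhere.
  Majority mapping replaces the external classifier some evaluation frameworks
  train on cluster-membership features — a deliberate simplification that
  removes a learner dependency while preserving "clusters explain outcome" as
  the measured quantity.
- `runtime_seconds` is carried in reports for information and excluded from
  all persisted files, keeping pipeline output byte-reproducible.

## Synthetic generator

The generator emulates the 12-attribute baseline panel: the ten published
chemistry/hematology cohort means and ranges, plus INR (range 0.8–6.0, mean
1.2) and aPTT (range 20–120 s, mean 28) — the coagulation ranges are package
conventions, not published statistics. Geometry is defined in the normalized
`[0, 10]` working domain and mapped affinely onto each attribute's physical
range, so planted structure survives the pipeline's own normalization.

Background objects are uniform per attribute (a maximally non-clustered null).
An alternative `"centered"` background draws a symmetric uniform about the
published mean (half-width capped by the range), reproducing the printed
cohort means in expectation — the generator's moment contract, checked to 2%
at n = 5000. Planted clusters are truncated normal (±3 spread, clipped to the
domain) in their relevant attributes and background elsewhere; planted blocks
are disjoint and recorded as `(O, S)` truth. Mortality is Bernoulli per
object: the cluster's rate inside planted groups, the background rate (default
0.14) outside — so outcome accuracy exceeds the majority baseline exactly when
found clusters align with outcome. `correlated_pair` couples two background
attributes through a Gaussian copula (uniform-background mode only; rank
correlation ρ, comonotone at ρ = 1), the scenario in which an intrinsically
coupled pair such as hemoglobin/hematocrit emerges as a 2-D density cluster.

What passing tests on this generator do **not** show: real TBI physiology has
correlated, skewed, unit-heterogeneous marginals, missingness that is
informative, and temporal structure; the generator models none of these except
the single optional copula pair. Recovery results certify algorithm
correctness on the assumed structure, not clinical performance.

## Problem sizes and numerical choices

The oracle-equivalence suite uses 50 randomized tables with n ≤ 200, d ≤ 6
across six (ε, MinPts) settings — exhaustive enumeration of up to 63 subspaces
stays exact and fast at that size. Recovery scenarios use two planted 2-D
clusters of 60 objects, spread 0.12, separation ≥ 10× spread, five seeds per
algorithm. The pipeline's cohort-scale demonstration uses n = 643, d = 12 with
the full 45-point density grid. Grid endpoint tolerance is 1e-9; all RNG flows
through `numpy.random.default_rng` with explicit seeds; JSON is written with
sorted keys and CSV with fixed float formatting so fixed-seed runs are
byte-identical.

## Known limitations

- SUBCLU enumerates every clustered subspace; on data with dense full-space
  structure and permissive ε the result set grows combinatorially (`max_dim`
  is the escape hatch).
- The cell-based miner's greedy ascending attribute scan can admit an early
  uninformative attribute when `τ` is small relative to the pool (see above);
  it also reports at most one cube per seed round.
- PROCLUS hill-climbing is a local search; different seeds can reach different
  local optima on weakly separated data.
- Entropy/accuracy compare clusters to a single binary outcome; they say
  nothing about multi-way or continuous outcomes.
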