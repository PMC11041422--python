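# labsubspace

Subspace clustering of clinical laboratory panels, built for phenotype
discovery in heterogeneous acute-care cohorts such as traumatic brain injury
(TBI) trials. Baseline physiology in such cohorts rarely clusters in the full
attribute space: clinically meaningful groups (a coagulopathy group visible in
INR, a fluid-resuscitation group visible in chloride and creatinine, the
intrinsic hemoglobin–hematocrit coupling) live in *subspaces* — small subsets
of the measured attributes. `labsubspace` implements the three standard
subspace-clustering families, a full-space k-means baseline, the evaluation
metrics used to compare them, and a synthetic cohort generator so the whole
analysis runs end-to-end with no restricted data.

## The model

A dataset is `DB ⊆ R^d` with attribute set `A`, `|A| = d`. Any `S ⊆ A` is a
subspace, and every cluster is an `(O, S)` pair: object set `O ⊆ DB`, relevant
attributes `S`. A clustering result `R` is a set of such pairs plus the noise
objects assigned to none.

- **Density-based (SUBCLU).** DBSCAN lifted to subspaces: with `dist^S` the
  metric restricted to `S`, the ε-neighborhood is
  `N^S_ε(p) = {q ∈ DB : dist^S(p,q) ≤ ε}`, `p` is core iff `|N^S_ε(p)| ≥
  MinPts`, and clusters are maximal density-connected sets. Because a cluster
  in `S` implies density-connected membership in every `T ⊂ S`
  (anti-monotonicity), SUBCLU enumerates all `(O, S)` bottom-up with
  Apriori-style candidate generation — exactly equivalent to running DBSCAN in
  all `2^d − 1` subspaces, which the test suite verifies against a brute-force
  oracle.
- **Cell-based (MineClus-style).** A cluster is the content of an
  axis-parallel hypercube of width `w` over its relevant attributes (full
  domain elsewhere) holding at least `τ` objects; cubes are grown greedily
  around seed objects and ranked by the quality `|O| · (1/β)^{|S|}`.
- **Clustering-oriented (PROCLUS-style).** k medoids with per-cluster
  subspaces of average size `l`, assignment by segmental distance (projected
  Manhattan / `|S|`), hill-climbing on the mean within-cluster dispersion.
- **Baseline.** Lloyd k-means on all attributes: coverage 1, subspace always
  the full `d`.

Evaluation against planted truth or an outcome label: macro **F1** of
best-matching found clusters, normalized label **entropy**, **coverage**,
**average dimensionality**, and majority-vote mortality **accuracy**.

Tables are min-max normalized per attribute to the 0–10 scale before
clustering; the density grids default to MinPts ∈ {8, 38, 68, 98, 128} and
ε ∈ {0.01, 0.04, …, 0.25}.

## Worked example

`examples/02_density_subspace.py` plants two tight 2-D clusters (sizes 60,
spread 0.12 normalized units) in disjoint attribute pairs of a 150-subject,
5-attribute panel and runs SUBCLU at ε = 0.25, MinPts = 8:

```
30 clusters across 10 subspaces; 0 noise objects
   74 objects in [glucose]
   71 objects in [sodium]
   70 objects in [creatinine]
   68 objects in [potassium]
   60 objects in [glucose, creatinine]
F1 against planted truth: 1.000
mortality accuracy:       0.787
```

The 1-D clusters are chains in single attributes; the 60-object cluster in
`[glucose, creatinine]` is one planted group recovered exactly, and F1 = 1.0
says both planted memberships were found. Accuracy 0.787 beats the 0.70
majority-label baseline because cluster membership carries the mortality
signal. The other examples cover the generator (`01`), cube mining (`03`),
PROCLUS versus k-means — where k-means' F1 collapses to 0.61 while PROCLUS
reaches 1.0 (`04`) — and the full sweep/report pipeline (`05`).

A thin CLI mirrors the pipeline: `labsubspace generate | cluster | evaluate |
run | grid` (see `labsubspace --help`), driven by a flat namespaced YAML
config.

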