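"""Projected k-medoid clustering (PROCLUS-style) versus full-space k-means.

On a table where every object belongs to one of two planted 2-D groups,
PROCLUS with k=2, l=2 finds both the memberships and the per-cluster
subspaces; full-space k-means sees mostly uniform noise dimensions and
fails to recover the partition — the study's core contrast.
"""

import labsubspace as ls

spec = ls.SyntheticSpec(
    n=120,
    attributes=tuple(ls.default_protect_panel()[:5]),
    planted=(
        ls.PlantedCluster(60, (0, 1), (3.0, 7.0), 0.12, mortality_rate=0.8),
        ls.PlantedCluster(60, (2, 3), (8.0, 2.0), 0.12, mortality_rate=0.1),
    ),
    seed=3,
)
table, truth = ls.generate(spec)
norm = ls.normalize(table)
names = norm.attribute_names

result, objective = ls.proclus(norm, ls.ProclusParams(k=2, l=2, seed=0))
print("PROCLUS (k=2, l=2):")
for c in result.clusters:
    labels = ", ".join(names[j] for j in c.subspace)
    print(f"  {len(c.objects)} objects projected on [{labels}]")
print(f"  objective (mean segmental dispersion): {objective.value:.4f}")
print(f"  F1 vs planted truth: {ls.f1_score(result, truth):.3f}")

km = ls.kmeans(norm, k=2, seed=0)
print("k-means (k=2, full space):")
print(f"  cluster sizes: {sorted(len(c.objects) for c in km.clusters)}")
print(f"  average dimensions: {ls.avg_dimensionality(km):.0f} (always d)")
print(f"  F1 vs planted truth: {ls.f1_score(km, truth):.3f}")
# PROCLUS reports each cluster with its own 2-attribute projection and a high
# F1; k-means spans all 5 attributes and its F1 shows the partition is driven
# by the uniform dimensions, not the planted structure.
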