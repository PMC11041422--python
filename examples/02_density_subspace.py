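"""Density-based subspace clustering (SUBCLU) recovering planted structure.

Plants two tight 2-D clusters in disjoint attribute pairs of a 5-attribute
panel, normalizes to the 0-10 scale, and runs SUBCLU with eps=0.25, minpts=8
(one corner of the study protocol's parameter grids).
"""

import labsubspace as ls

spec = ls.SyntheticSpec(
    n=150,
    attributes=tuple(ls.default_protect_panel()[:5]),
    planted=(
        ls.PlantedCluster(60, (0, 1), (3.0, 7.0), 0.12, mortality_rate=0.8),
        ls.PlantedCluster(60, (2, 3), (8.0, 2.0), 0.12, mortality_rate=0.1),
    ),
    seed=1,
)
table, truth = ls.generate(spec)
norm = ls.normalize(table)

result = ls.subclu(norm, ls.DensityParams(eps=0.25, minpts=8))
print(f"{result.n_clusters} clusters across "
      f"{len({c.subspace for c in result.clusters})} subspaces; "
      f"{len(result.noise)} noise objects")

names = norm.attribute_names
for c in sorted(result.clusters, key=lambda c: -len(c.objects))[:5]:
    labels = ", ".join(names[j] for j in c.subspace)
    print(f"  {len(c.objects):3d} objects in [{labels}]")

print(f"F1 against planted truth: {ls.f1_score(result, truth):.3f}")
print(f"mortality accuracy:       {ls.outcome_accuracy(result, truth):.3f}")
# The two largest multi-attribute clusters sit exactly in the planted
# attribute pairs; F1 near 1 means memberships were recovered almost exactly.
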