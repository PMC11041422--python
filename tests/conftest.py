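"""Shared fixtures: tiny hand-constructed tables and planted-cluster scenarios."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

import labsubspace as ls


def make_table(values, names=None, ids=None, **meta) -> ls.LabTable:
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n, d = values.shape
    return ls.LabTable(
        values=values,
        attribute_names=names or [f"a{j}" for j in range(d)],
        subject_ids=ids or [f"s{i}" for i in range(n)],
        **meta,
    )


def exhaustive_subspace_dbscan(table: ls.LabTable, params: ls.DensityParams):
    """Brute-force oracle: run DBSCAN independently on every one of the
    2^d - 1 non-empty subspaces and collect all (objects, subspace) pairs."""
    d = table.n_attributes
    found = set()
    for k in range(1, d + 1):
        for sub in combinations(range(d), k):
            res = ls.dbscan_subspace(table, sub, params)
            for c in res.clusters:
                found.add((c.objects, c.subspace))
    return found


def two_planted_spec(seed: int, n: int = 150, background: bool = True) -> ls.SyntheticSpec:
    """Two well-separated planted 2-D clusters (spread 0.12, separation >= 10x
    spread) in disjoint attribute pairs of a 5-attribute panel, sizes 60."""
    planted = (
        ls.PlantedCluster(60, (0, 1), (3.0, 7.0), 0.12, mortality_rate=0.8),
        ls.PlantedCluster(60, (2, 3), (8.0, 2.0), 0.12, mortality_rate=0.1),
    )
    return ls.SyntheticSpec(
        n=n if background else 120,
        attributes=tuple(ls.default_protect_panel()[:5]),
        planted=planted,
        seed=seed,
    )


@pytest.fixture
def line_1d() -> ls.LabTable:
    """Six 1-D points in two tight groups: {0,1,2} and {50,51,52}."""
    return make_table([0.0, 1.0, 2.0, 50.0, 51.0, 52.0])


@pytest.fixture
def planted_table():
    """Normalized 150x5 table with the two planted 2-D clusters, plus truth."""
    table, truth = ls.generate(two_planted_spec(seed=1))
    return ls.normalize(table), truth
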