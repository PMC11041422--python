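"""Density-based subspace clustering: projected DBSCAN and the SUBCLU search.

The load-bearing check is oracle equivalence: SUBCLU's output must equal
exhaustive per-subspace DBSCAN over all 2^d - 1 subspaces for any parameters.
"""

import numpy as np
import pytest

import labsubspace as ls
from conftest import exhaustive_subspace_dbscan, make_table


class TestProjectedDistance:
    def test_pythagorean_and_projection(self):
        t = make_table([[0.0, 0.0], [3.0, 4.0]])
        assert ls.projected_distance(0, 1, (0, 1), t) == pytest.approx(5.0)
        assert ls.projected_distance(0, 1, (0,), t) == pytest.approx(3.0)
        assert ls.projected_distance(0, 1, (0, 1), t, metric="manhattan") == 7.0

    def test_identity_and_symmetry(self):
        t = make_table([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        for sub in [(0,), (1, 2), (0, 1, 2)]:
            assert ls.projected_distance(0, 0, sub, t) == 0.0
            assert ls.projected_distance(0, 1, sub, t) == ls.projected_distance(
                1, 0, sub, t
            )

    def test_empty_subspace_rejected(self):
        t = make_table([[1.0], [2.0]])
        with pytest.raises(ValueError):
            ls.projected_distance(0, 1, (), t)


class TestEpsNeighborhood:
    def test_enumerated_1d_case(self):
        t = make_table([0.0, 1.0, 2.0, 50.0])
        got = ls.eps_neighborhood(1, (0,), ls.DensityParams(eps=1, minpts=1), t)
        assert got == {0, 1, 2}

    def test_zero_radius_and_full_cover(self):
        t = make_table([0.0, 0.0, 5.0])
        p0 = ls.DensityParams(eps=0, minpts=1)
        assert ls.eps_neighborhood(0, (0,), p0, t) == {0, 1}
        pbig = ls.DensityParams(eps=100, minpts=1)
        assert ls.eps_neighborhood(0, (0,), pbig, t) == {0, 1, 2}

    def test_boundary_distance_included(self):
        t = make_table([0.0, 2.0])
        got = ls.eps_neighborhood(0, (0,), ls.DensityParams(eps=2, minpts=1), t)
        assert got == {0, 1}


class TestDbscanSubspace:
    def test_two_groups_no_noise(self, line_1d):
        res = ls.dbscan_subspace(line_1d, (0,), ls.DensityParams(eps=2, minpts=3))
        assert sorted(sorted(c.objects) for c in res.clusters) == [
            [0, 1, 2],
            [3, 4, 5],
        ]
        assert res.noise == frozenset()

    def test_minpts_above_n_all_noise(self, line_1d):
        res = ls.dbscan_subspace(line_1d, (0,), ls.DensityParams(eps=2, minpts=7))
        assert res.clusters == [] and res.noise == frozenset(range(6))

    def test_single_component(self, line_1d):
        res = ls.dbscan_subspace(line_1d, (0,), ls.DensityParams(eps=100, minpts=1))
        assert len(res.clusters) == 1
        assert res.clusters[0].objects == frozenset(range(6))

    def test_matches_bruteforce_reachability_closure(self):
        """Cross-check against a literal reachability-closure implementation."""
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 10, size=(40, 2))
        t = make_table(X)
        params = ls.DensityParams(eps=1.5, minpts=4)
        res = ls.dbscan_subspace(t, (0, 1), params)
        # brute force: cores, then closure of core adjacency, borders attached
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        adj = D <= params.eps
        core = adj.sum(1) >= params.minpts
        comps = []
        seen = set()
        for i in np.flatnonzero(core):
            if i in seen:
                continue
            comp, frontier = {int(i)}, [int(i)]
            while frontier:
                j = frontier.pop()
                for nb in np.flatnonzero(adj[j] & core):
                    if int(nb) not in comp:
                        comp.add(int(nb))
                        frontier.append(int(nb))
            seen |= comp
            comps.append(comp)
        core_clusters = {frozenset(c) for c in comps}
        got_cores = {frozenset(o for o in c.objects if core[o]) for c in res.clusters}
        assert got_cores == core_clusters
        # every border member must be adjacent to a core of its cluster
        for c in res.clusters:
            for o in c.objects:
                if not core[o]:
                    assert any(adj[o, q] for q in c.objects if core[q])

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 10, size=(60, 3))
        t = make_table(X)
        params = ls.DensityParams(eps=1.2, minpts=3)
        base = {frozenset(c.objects) for c in ls.dbscan_subspace(t, (0, 2), params).clusters}
        perm = rng.permutation(60)
        tp = make_table(X[perm])
        mapped = {
            frozenset(int(perm[o]) for o in c.objects)
            for c in ls.dbscan_subspace(tp, (0, 2), params).clusters
        }
        assert base == mapped

    def test_eps_monotone_in_clustered_objects_1d(self):
        rng = np.random.default_rng(11)
        t = make_table(rng.uniform(0, 10, size=80))
        prev = -1
        for eps in [0.05, 0.1, 0.2, 0.4, 0.8, 1.6]:
            res = ls.dbscan_subspace(t, (0,), ls.DensityParams(eps=eps, minpts=4))
            clustered = len(res.covered_objects())
            assert clustered >= prev
            prev = clustered


class TestGenerateCandidates:
    @pytest.mark.parametrize(
        "inputs,expected",
        [
            ([(0,), (1,)], [(0, 1)]),
            ([(0, 1), (0, 2), (1, 2)], [(0, 1, 2)]),
            ([(0, 1), (2, 3)], []),  # no shared attribute to join on
            ([(0, 1), (0, 2)], []),  # (1,2) missing: pruned
        ],
    )
    def test_join_and_prune(self, inputs, expected):
        assert ls.generate_candidates(inputs) == expected

    def test_mixed_dimensionality_rejected(self):
        with pytest.raises(ValueError):
            ls.generate_candidates([(0,), (1, 2)])


class TestSubclu:
    def test_level1_equals_per_attribute_dbscan(self, line_1d):
        params = ls.DensityParams(eps=2, minpts=3)
        res = ls.subclu(line_1d, params, max_dim=1)
        direct = ls.dbscan_subspace(line_1d, (0,), params)
        assert {(c.objects, c.subspace) for c in res.clusters} == {
            (c.objects, c.subspace) for c in direct.clusters
        }

    def test_too_few_points_empty_result(self):
        t = make_table([[1.0, 2.0], [1.1, 2.1]])
        res = ls.subclu(t, ls.DensityParams(eps=1, minpts=5))
        assert res.clusters == [] and res.noise == frozenset({0, 1})

    def test_finds_planted_2d_cluster(self, planted_table):
        table, truth = planted_table
        res = ls.subclu(table, ls.DensityParams(eps=0.25, minpts=8))
        for hidden in truth.hidden_clusters:
            match = [
                c for c in res.clusters
                if c.subspace == hidden.subspace
                and len(c.objects & hidden.objects) >= 0.9 * len(hidden.objects)
            ]
            assert match, f"no cluster recovered in subspace {hidden.subspace}"

    @pytest.mark.parametrize("eps,minpts", [(0.3, 4), (1.0, 5), (2.5, 3)])
    def test_oracle_equivalence_random_tables(self, eps, minpts):
        """SUBCLU equals exhaustive per-subspace DBSCAN (the defining property)."""
        rng = np.random.default_rng(minpts * 100 + int(eps * 10))
        for _ in range(3):
            n, d = int(rng.integers(20, 90)), int(rng.integers(2, 5))
            X = rng.uniform(0, 10, size=(n, d))
            X[: n // 4, : min(2, d)] = rng.normal(5, 0.15, size=(n // 4, min(2, d)))
            t = make_table(X)
            params = ls.DensityParams(eps=eps, minpts=minpts)
            got = {(c.objects, c.subspace) for c in ls.subclu(t, params).clusters}
            assert got == exhaustive_subspace_dbscan(t, params)

    def test_density_monotonicity_across_subspaces(self):
        """Objects clustered in S are non-noise in every proper subset of S."""
        rng = np.random.default_rng(42)
        X = rng.uniform(0, 10, size=(70, 3))
        X[:25] = rng.normal(4, 0.2, size=(25, 3))
        t = make_table(X)
        params = ls.DensityParams(eps=0.8, minpts=5)
        res = ls.subclu(t, params)
        from itertools import combinations

        for c in res.clusters:
            for k in range(1, len(c.subspace)):
                for sub in combinations(c.subspace, k):
                    r = ls.dbscan_subspace(t, sub, params)
                    assert c.objects <= r.covered_objects()

    def test_max_dim_caps_search(self, planted_table):
        table, _ = planted_table
        res = ls.subclu(table, ls.DensityParams(eps=0.25, minpts=8), max_dim=1)
        assert all(len(c.subspace) == 1 for c in res.clusters)
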