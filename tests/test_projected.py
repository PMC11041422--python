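"""Projected k-medoid clustering (PROCLUS-style) and the full-space k-means baseline."""

import numpy as np
import pytest

import labsubspace as ls
from labsubspace.projected import farthest_first
from conftest import make_table, two_planted_spec


class TestMedoidPool:
    def test_farthest_first_on_collinear_points(self):
        # values 0, 1, 10: starting at 0, the farthest is 10, then 1
        X = np.array([[0.0], [1.0], [10.0]])
        assert farthest_first(X, np.array([0, 1, 2]), 3) == [0, 2, 1]

    def test_single_medoid(self):
        t = make_table(np.arange(10.0))
        pool = ls.greedy_medoid_pool(t, ls.ProclusParams(k=1, l=2, seed=0,
                                                         sample_factor_b=1))
        assert len(pool) == 1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        t = make_table(rng.uniform(0, 10, size=(50, 3)))
        p = ls.ProclusParams(k=3, l=2, seed=5)
        assert ls.greedy_medoid_pool(t, p) == ls.greedy_medoid_pool(t, p)


class TestFindDimensions:
    def test_slot_cardinality(self):
        rng = np.random.default_rng(1)
        t = make_table(rng.uniform(0, 10, size=(60, 5)))
        params = ls.ProclusParams(k=2, l=3, seed=0)
        subs = ls.find_dimensions([3, 40], t, params)
        assert sum(len(s) for s in subs) == 6
        assert all(len(s) >= 2 for s in subs)

    def test_zero_spread_attributes_selected(self):
        """A 20-point locality flat in attributes {0,1} and wide elsewhere must
        hand the medoid exactly {0,1} at l=2."""
        rng = np.random.default_rng(4)
        near = np.column_stack([
            np.full(20, 5.0), np.full(20, 5.0),
            rng.uniform(0, 10, 20), rng.uniform(0, 10, 20),
        ])
        far = np.column_stack([
            np.full(20, 9.0), np.full(20, 1.0),
            rng.uniform(0, 10, 20), rng.uniform(0, 10, 20),
        ])
        t = make_table(np.vstack([near, far]))
        subs = ls.find_dimensions([0, 20], t, ls.ProclusParams(k=2, l=2, seed=0))
        assert subs[0] == (0, 1)

    def test_l_equals_d_single_medoid_takes_all(self):
        rng = np.random.default_rng(6)
        t = make_table(rng.uniform(0, 10, size=(30, 4)))
        subs = ls.find_dimensions([0], t, ls.ProclusParams(k=1, l=4, seed=0))
        assert subs == [(0, 1, 2, 3)]


class TestAssignPoints:
    def test_tie_goes_to_lower_medoid_and_self_distance_zero(self):
        t = make_table([[0.0], [5.0], [10.0]])
        res = ls.assign_points(t, [0, 2], [(0,), (0,)])
        by_medoid = {min(c.objects): c.objects for c in res.clusters}
        assert 1 in by_medoid[0]  # equidistant object joins the lower medoid
        assert 0 in by_medoid[0] and 2 in by_medoid[2]

    def test_planted_assignment(self):
        table, truth = ls.generate(two_planted_spec(seed=2, background=False))
        table = ls.normalize(table)
        medoids = [0, 60]  # one object inside each planted block
        res = ls.assign_points(table, medoids, [(0, 1), (2, 3)])
        got = {frozenset(c.objects) for c in res.clusters}
        want = {h.objects for h in truth.hidden_clusters}
        assert got == want


class TestProclus:
    def test_forced_single_cluster_configuration(self):
        rng = np.random.default_rng(10)
        t = make_table(rng.uniform(0, 10, size=(40, 3)))
        res, _ = ls.proclus(t, ls.ProclusParams(k=1, l=3, seed=0))
        assert res.n_clusters == 1
        assert res.clusters[0].objects == frozenset(range(40))
        assert res.clusters[0].subspace == (0, 1, 2)

    def test_parameter_recovery_five_seeds(self):
        table, truth = ls.generate(two_planted_spec(seed=3, background=False))
        table = ls.normalize(table)
        for seed in range(5):
            res, _ = ls.proclus(table, ls.ProclusParams(k=2, l=2, seed=seed))
            assert ls.f1_score(res, truth) >= 0.9

    def test_average_dimensionality_equals_l(self):
        rng = np.random.default_rng(12)
        t = make_table(rng.uniform(0, 10, size=(90, 6)))
        params = ls.ProclusParams(k=3, l=3, seed=1)
        res, _ = ls.proclus(t, params)
        assert ls.avg_dimensionality(res) == pytest.approx(params.l)

    def test_hill_climbing_never_worsens(self):
        rng = np.random.default_rng(13)
        t = make_table(rng.uniform(0, 10, size=(80, 4)))
        params = ls.ProclusParams(k=3, l=2, seed=7)
        # initial medoid set = first k of the pool; its objective bounds the result
        from labsubspace.projected import _segmental, _objective

        pool = ls.greedy_medoid_pool(t, params)
        meds = pool[: params.k]
        subs = ls.find_dimensions(meds, t, params)
        D = _segmental(t.values, meds, subs)
        nearest = np.argmin(D, axis=1)
        initial = _objective(t.values, meds, subs, nearest, D)
        _, obj = ls.proclus(t, params)
        assert obj.value <= initial + 1e-12

    def test_bit_reproducible(self):
        rng = np.random.default_rng(14)
        t = make_table(rng.uniform(0, 10, size=(70, 4)))
        p = ls.ProclusParams(k=2, l=2, seed=21)
        a, oa = ls.proclus(t, p)
        b, ob = ls.proclus(t, p)
        assert a.to_dict() == b.to_dict() and oa == ob


class TestKmeans:
    def test_k1_center_is_mean_and_kn_zero_wcss(self):
        rng = np.random.default_rng(15)
        t = make_table(rng.uniform(0, 10, size=(12, 3)))
        res1 = ls.kmeans(t, k=1, seed=0)
        assert res1.n_clusters == 1 and res1.clusters[0].objects == frozenset(range(12))
        resn = ls.kmeans(t, k=12, seed=0)
        assert resn.params["wcss"] == pytest.approx(0.0)
        assert resn.n_clusters == 12

    def test_recovers_separated_groups_and_cross_checks_sklearn(self):
        from sklearn.cluster import KMeans

        # full-space separation (planted in every attribute): k-means' regime
        planted = (
            ls.PlantedCluster(60, (0, 1, 2, 3, 4), (2.0,) * 5, 0.15),
            ls.PlantedCluster(60, (0, 1, 2, 3, 4), (8.0,) * 5, 0.15),
        )
        spec = ls.SyntheticSpec(
            n=120, attributes=tuple(ls.default_protect_panel()[:5]),
            planted=planted, seed=4,
        )
        table, truth = ls.generate(spec)
        table = ls.normalize(table)
        want = {h.objects for h in truth.hidden_clusters}
        for seed in range(5):
            res = ls.kmeans(table, k=2, seed=seed)
            assert {c.objects for c in res.clusters} == want
        # independent implementation agrees on the optimum objective
        sk = KMeans(n_clusters=2, n_init=10, random_state=0).fit(table.values)
        assert ls.kmeans(table, k=2, seed=0).params["wcss"] == pytest.approx(
            sk.inertia_, rel=1e-6
        )

    def test_full_space_full_coverage(self):
        rng = np.random.default_rng(16)
        t = make_table(rng.uniform(0, 10, size=(50, 7)))
        res = ls.kmeans(t, k=5, seed=2)
        assert ls.avg_dimensionality(res) == 7.0
        assert ls.coverage(res, 50) == 1.0 and res.noise == frozenset()

    def test_k_bounds(self):
        t = make_table(np.arange(5.0))
        with pytest.raises(ValueError):
            ls.kmeans(t, k=6)
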