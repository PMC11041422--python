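"""Clustering-oriented (projected) partitioning: a PROCLUS-style k-medoid
algorithm with target average dimensionality l, and the full-space k-means
baseline.

PROCLUS partitions the data into k clusters, each with its own axis-parallel
subspace, such that the average subspace size is l.  It samples a candidate
medoid pool by farthest-first traversal, picks per-medoid dimensions from the
attributes with anomalously small mean absolute deviation in the medoid's
locality, assigns every object by *segmental* distance (projected Manhattan
distance divided by the subspace size, making subspaces of different sizes
comparable), and hill-climbs by swapping out the medoid of the smallest
cluster.  k-means is the conventional Lloyd iteration on all attributes; its
clusters always span the full attribute space and cover every object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .results import ClusteringResult, Subspace, SubspaceCluster
from .table import LabTable

__all__ = [
    "ProclusParams",
    "ObjectiveValue",
    "greedy_medoid_pool",
    "farthest_first",
    "find_dimensions",
    "assign_points",
    "proclus",
    "kmeans",
]


@dataclass(frozen=True)
class ProclusParams:
    """k clusters, average dimensionality l (>= 2 so each cluster can keep the
    mandatory two attributes), candidate pool sizes A = a*k and B = b*k,
    hill-climbing budget, bad-medoid threshold factor, RNG seed."""

    k: int
    l: int
    sample_factor_a: int = 30
    sample_factor_b: int = 3
    max_iter: int = 20
    min_deviation: float = 0.1
    seed: int = 0
    outlier_handling: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.l < 2:
            raise ValueError("l must be >= 2 (two attributes per cluster minimum)")
        if not 0 < self.min_deviation <= 1:
            raise ValueError("min_deviation must lie in (0, 1]")


@dataclass(frozen=True)
class ObjectiveValue:
    """Mean within-cluster dispersion over each cluster's selected dimensions."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("objective must be non-negative")


def farthest_first(X: np.ndarray, pool: np.ndarray, b: int) -> list[int]:
    """Greedy selection of ``b`` indices from ``pool`` maximizing the minimum
    full-space Euclidean distance to those already chosen; starts from
    ``pool[0]``; ties go to the earlier pool position."""
    pool = np.asarray(pool, dtype=np.int64)
    chosen = [int(pool[0])]
    rest = pool[1:]
    if b <= 1 or rest.size == 0:
        return chosen[:b]
    mind = cdist(X[rest], X[[chosen[0]]]).ravel()
    alive = np.ones(rest.size, dtype=bool)
    while len(chosen) < b and alive.any():
        pos = int(np.flatnonzero(alive)[np.argmax(mind[alive])])
        chosen.append(int(rest[pos]))
        alive[pos] = False
        if alive.any():
            d_new = cdist(X[rest[alive]], X[[chosen[-1]]]).ravel()
            mind[alive] = np.minimum(mind[alive], d_new)
    return chosen


def greedy_medoid_pool(
    table: LabTable, params: ProclusParams, rng: np.random.Generator | None = None
) -> list[int]:
    """Sample A = a*k objects uniformly (seeded), then farthest-first down to
    B = b*k well-spread candidate medoids."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = table.n_subjects
    a_size = min(params.sample_factor_a * params.k, n)
    b_size = min(max(params.sample_factor_b * params.k, params.k), a_size)
    if b_size > n:
        raise ValueError("candidate pool larger than the data")
    pool = rng.choice(n, size=a_size, replace=False)
    return farthest_first(table.values, pool, b_size)


def _localities(X: np.ndarray, medoids: list[int]) -> list[np.ndarray]:
    """Voronoi localities: each object joins its nearest medoid (full-space
    Euclidean, ties to the lower medoid index).  Each medoid sits in its own
    locality unless it duplicates a lower-indexed medoid's coordinates."""
    D = cdist(X, X[medoids])
    nearest = np.argmin(D, axis=1)  # argmin takes the first minimum: lower index
    return [np.flatnonzero(nearest == i) for i in range(len(medoids))]


def find_dimensions(
    medoids: list[int], table: LabTable, params: ProclusParams
) -> list[Subspace]:
    """Per-medoid subspace selection.

    For each medoid, the mean absolute deviation from the medoid per attribute
    is computed over its locality and standardized across attributes (z-score
    per medoid).  The k*l globally smallest standardized deviations are
    selected subject to every medoid keeping at least two attributes.
    """
    X = table.values
    k, d = len(medoids), table.n_attributes
    if params.l > d:
        raise ValueError("l cannot exceed the number of attributes")
    locs = _localities(X, medoids)
    for i, loc in enumerate(locs):
        if loc.size == 0:
            raise ValueError(f"empty locality for medoid {medoids[i]}")
    Z = np.empty((k, d))
    for i, loc in enumerate(locs):
        dev = np.abs(X[loc] - X[medoids[i]]).mean(axis=0)
        mu, sd = dev.mean(), dev.std(ddof=1) if d > 1 else 0.0
        Z[i] = (dev - mu) / sd if sd > 0 else np.zeros(d)

    chosen: list[list[int]] = [[] for _ in range(k)]
    order = np.argsort(Z, axis=1, kind="stable")
    # mandatory two smallest per medoid
    for i in range(k):
        chosen[i] = [int(order[i, 0]), int(order[i, 1])]
    # remaining k*l - 2k slots by globally smallest remaining z-scores
    remaining = params.k * params.l - 2 * k
    flat = sorted(
        ((float(Z[i, j]), i, j) for i in range(k) for j in range(d)
         if j not in chosen[i]),
    )
    for _, i, j in flat[: max(remaining, 0)]:
        chosen[i].append(j)
    return [tuple(sorted(c)) for c in chosen]


def _segmental(X: np.ndarray, medoids: list[int], subspaces: list[Subspace]
               ) -> np.ndarray:
    """(n, k) matrix of segmental distances: projected Manhattan / |subspace|."""
    n = X.shape[0]
    D = np.empty((n, len(medoids)))
    for i, (m, sub) in enumerate(zip(medoids, subspaces)):
        cols = list(sub)
        D[:, i] = np.abs(X[:, cols] - X[m, cols]).sum(axis=1) / len(cols)
    return D


def assign_points(
    table: LabTable,
    medoids: list[int],
    subspaces: list[Subspace],
    outlier_handling: bool = False,
) -> ClusteringResult:
    """Assign every object to the medoid of minimum segmental distance (ties to
    the lower medoid index).  With outlier handling on, objects whose segmental
    distance to their medoid exceeds that medoid's locality radius (largest
    segmental distance from the medoid to its own Voronoi locality) become
    noise instead."""
    X = table.values
    D = _segmental(X, medoids, subspaces)
    nearest = np.argmin(D, axis=1)
    noise: set[int] = set()
    if outlier_handling:
        locs = _localities(X, medoids)
        for i, loc in enumerate(locs):
            radius = float(D[loc, i].max()) if loc.size else 0.0
            members = np.flatnonzero(nearest == i)
            for o in members[D[members, i] > radius]:
                noise.add(int(o))
    clusters = []
    for i in range(len(medoids)):
        objs = frozenset(
            int(o) for o in np.flatnonzero(nearest == i) if int(o) not in noise
        )
        if objs:
            clusters.append(SubspaceCluster(objs, subspaces[i]))
    return ClusteringResult(clusters=clusters, noise=frozenset(noise),
                            algorithm="proclus")


def _objective(X: np.ndarray, medoids: list[int], subspaces: list[Subspace],
               nearest: np.ndarray, D: np.ndarray) -> float:
    """Unweighted mean over clusters of the mean segmental distance to the medoid."""
    vals = []
    for i in range(len(medoids)):
        members = np.flatnonzero(nearest == i)
        if members.size:
            vals.append(float(D[members, i].mean()))
    return float(np.mean(vals)) if vals else 0.0


def proclus(
    table: LabTable, params: ProclusParams
) -> tuple[ClusteringResult, ObjectiveValue]:
    """PROCLUS-style hill-climbing over medoid sets.

    Starts from the first k pool candidates; each iteration recomputes
    dimensions/assignment/objective, then swaps the medoid of the smallest
    cluster (the "bad" medoid, certainly so when its cluster falls below
    ``min_deviation * n / k``) for a random unused pool candidate.  The best
    medoid set seen is kept; the search stops after ``max_iter`` consecutive
    non-improving swaps.
    """
    rng = np.random.default_rng(params.seed)
    X = table.values
    n = table.n_subjects
    if params.k > n:
        raise ValueError("k cannot exceed the number of objects")
    pool = greedy_medoid_pool(table, params, rng=rng)
    if len(pool) < params.k:
        raise ValueError("candidate pool smaller than k")
    medoids = list(pool[: params.k])

    def evaluate(meds: list[int]) -> tuple[float, list[Subspace], np.ndarray, np.ndarray]:
        subs = find_dimensions(meds, table, params)
        D = _segmental(X, meds, subs)
        nearest = np.argmin(D, axis=1)
        return _objective(X, meds, subs, nearest, D), subs, nearest, D

    best_obj, best_subs, best_nearest, best_D = evaluate(medoids)
    best_medoids = list(medoids)
    non_improving = 0
    while non_improving < params.max_iter:
        unused = [p for p in pool if p not in best_medoids]
        if not unused:
            break
        sizes = np.bincount(best_nearest, minlength=params.k)
        bad = int(np.argmin(sizes))  # smallest cluster; spec threshold flags it
        trial = list(best_medoids)
        trial[bad] = int(unused[rng.integers(len(unused))])
        try:
            obj, subs, nearest, D = evaluate(trial)
        except ValueError:  # degenerate locality: reject the swap
            non_improving += 1
            continue
        if obj < best_obj - 1e-12:
            best_obj, best_subs, best_nearest, best_D = obj, subs, nearest, D
            best_medoids = trial
            non_improving = 0
        else:
            non_improving += 1

    result = assign_points(
        table, best_medoids, best_subs, outlier_handling=params.outlier_handling
    )
    result.algorithm = "proclus"
    result.params = {
        "k": params.k, "l": params.l, "seed": params.seed,
        "outlier_handling": params.outlier_handling,
        "medoids": [int(m) for m in best_medoids],
    }
    return result, ObjectiveValue(best_obj)


def kmeans(
    table: LabTable,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 300,
) -> ClusteringResult:
    """Full-space Lloyd k-means, best of ``n_restarts`` seeded random starts.

    Every cluster's subspace is all attributes and every object is assigned
    (coverage 1, no noise).  The within-cluster sum of squares is checked to be
    non-increasing across Lloyd iterations.
    """
    X = table.values
    n, d = X.shape
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    rng = np.random.default_rng(seed)
    full: Subspace = tuple(range(d))
    best_labels, best_wcss = None, np.inf
    for _ in range(n_restarts):
        centers = X[rng.choice(n, size=k, replace=False)].copy()
        prev = np.inf
        for _ in range(max_iter):
            D2 = cdist(X, centers, metric="sqeuclidean")
            labels = np.argmin(D2, axis=1)
            wcss = float(D2[np.arange(n), labels].sum())
            if wcss > prev + 1e-9:
                raise AssertionError("Lloyd objective increased")
            for i in range(k):
                members = X[labels == i]
                if len(members):
                    centers[i] = members.mean(axis=0)
                else:  # re-seed an empty cluster at the worst-fit point
                    centers[i] = X[int(np.argmax(D2[np.arange(n), labels]))]
            if prev - wcss <= 1e-12:
                break
            prev = wcss
        if wcss < best_wcss:
            best_wcss, best_labels = wcss, labels
    clusters = [
        SubspaceCluster(frozenset(int(o) for o in np.flatnonzero(best_labels == i)),
                        full)
        for i in range(k)
        if np.any(best_labels == i)
    ]
    return ClusteringResult(
        clusters=clusters,
        noise=frozenset(),
        algorithm="kmeans",
        params={"k": k, "seed": seed, "n_restarts": n_restarts,
                "wcss": best_wcss},
    )
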