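"""Cell-based projective clustering in the DOC/MineClus style.

A cell-based cluster is the set of objects caught by an axis-parallel hypercube
of fixed width ``w`` over a *relevant* attribute subset, full-domain elsewhere,
holding at least ``tau`` objects.  Candidate cubes are anchored at randomly
drawn seed objects; per seed, attributes are admitted greedily (ascending
index) whenever the cube restricted to the accepted attributes still holds at
least ``tau`` objects.  Among the seeds of one round the cube maximizing the
quality ``|O| * (1/beta)^|S|`` is emitted, its objects removed, and mining
repeats until no cube reaches ``tau`` support; leftover objects are noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .results import ClusteringResult, Subspace, SubspaceCluster, as_subspace
from .table import LabTable

__all__ = ["CellParams", "Hypercube", "cube_membership", "quality",
           "best_cube_for_seed", "mineclus"]


@dataclass(frozen=True)
class CellParams:
    """Cube width ``w`` (normalized units), minimum support ``tau``, size/dimension
    trade-off ``beta`` in (0,1), seeds drawn per mining round, RNG seed, and the
    normalization upper bound ``v`` delimiting the attribute domain [0, v]."""

    w: float
    tau: int
    beta: float = 0.25
    n_seeds: int = 10
    seed: int = 0
    v: float = 10.0

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("w must be > 0")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie in (0, 1)")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


@dataclass(frozen=True)
class Hypercube:
    """Axis-parallel cube: closed interval ``[l_i, u_i]`` of width w per relevant
    attribute, implicitly the full domain ``[0, v]`` elsewhere."""

    intervals: tuple[tuple[float, float], ...]  # aligned with `relevant`
    relevant: Subspace
    v: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "relevant", as_subspace(self.relevant))
        if len(self.intervals) != len(self.relevant):
            raise ValueError("one interval per relevant attribute required")
        for lo, hi in self.intervals:
            if lo < -1e-12 or hi > self.v + 1e-12:
                raise ValueError("interval outside the [0, v] domain")


def cube_membership(o: int, cube: Hypercube, table: LabTable) -> bool:
    """True iff the object lies inside every relevant closed interval.
    A cube with no relevant attributes covers the whole domain."""
    x = table.values[o]
    return all(
        lo <= x[a] <= hi for a, (lo, hi) in zip(cube.relevant, cube.intervals)
    )


def quality(n_objects: int, n_dims: int, beta: float) -> float:
    """DOC-lineage cube score ``n * (1/beta)^d`` — strictly increasing in both
    the member count and the number of relevant dimensions."""
    if n_objects < 0 or n_dims < 0:
        raise ValueError("counts must be non-negative")
    if not 0 < beta < 1:
        raise ValueError("beta must lie in (0, 1)")
    return n_objects * (1.0 / beta) ** n_dims


def _seed_interval(x: float, w: float, v: float) -> tuple[float, float]:
    """Width-w window centered on the seed value, shifted to fit inside [0, v]
    (window wider than the domain collapses to the domain)."""
    if w >= v:
        return 0.0, v
    lo = min(max(x - w / 2.0, 0.0), v - w)
    return lo, lo + w


def best_cube_for_seed(
    seed_obj: int,
    table: LabTable,
    params: CellParams,
    restrict_to: np.ndarray | None = None,
) -> tuple[Hypercube, frozenset[int]] | None:
    """Greedy relevant-attribute selection for the cube anchored at one seed.

    Attributes are scanned in ascending index; attribute j is accepted when at
    least ``tau`` of the objects already inside the cube also fall inside the
    seed-centered width-w window on j.  Returns None when no attribute can be
    accepted or the final cube holds fewer than ``tau`` objects.
    """
    X = table.values
    if restrict_to is None:
        members = np.arange(table.n_subjects)
    else:
        members = np.asarray(sorted(restrict_to), dtype=np.int64)
    x_seed = X[seed_obj]
    relevant: list[int] = []
    intervals: list[tuple[float, float]] = []
    for j in range(table.n_attributes):
        lo, hi = _seed_interval(float(x_seed[j]), params.w, params.v)
        inside = members[(X[members, j] >= lo) & (X[members, j] <= hi)]
        if inside.size >= params.tau:
            relevant.append(j)
            intervals.append((lo, hi))
            members = inside
    if not relevant or members.size < params.tau:
        return None
    cube = Hypercube(tuple(intervals), tuple(relevant), v=params.v)
    return cube, frozenset(int(i) for i in members)


def mineclus(table: LabTable, params: CellParams) -> ClusteringResult:
    """Iterative cube mining with removal semantics (clusters are disjoint).

    Each round draws ``n_seeds`` seed objects without replacement from the
    not-yet-clustered pool, builds the greedy cube for each, and emits the best
    by :func:`quality`; ties keep the earliest-drawn seed.  Mining stops when no
    cube reaches ``tau`` support.
    """
    rng = np.random.default_rng(params.seed)
    alive = np.arange(table.n_subjects)
    clusters: list[SubspaceCluster] = []
    while alive.size >= params.tau:
        n_draw = min(params.n_seeds, alive.size)
        seeds = rng.choice(alive, size=n_draw, replace=False)
        best: tuple[float, Hypercube, frozenset[int]] | None = None
        for s in seeds:
            got = best_cube_for_seed(int(s), table, params, restrict_to=alive)
            if got is None:
                continue
            cube, objs = got
            q = quality(len(objs), len(cube.relevant), params.beta)
            if best is None or q > best[0]:
                best = (q, cube, objs)
        if best is None:
            break
        _, cube, objs = best
        clusters.append(SubspaceCluster(objs, cube.relevant))
        alive = alive[~np.isin(alive, np.fromiter(objs, dtype=np.int64))]
    covered: set[int] = set()
    for c in clusters:
        covered |= c.objects
    return ClusteringResult(
        clusters=clusters,
        noise=frozenset(range(table.n_subjects)) - covered,
        algorithm="mineclus",
        params={"w": params.w, "tau": params.tau, "beta": params.beta,
                "n_seeds": params.n_seeds, "seed": params.seed},
    )
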