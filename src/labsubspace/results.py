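"""Cluster result containers shared by every algorithm family.

A subspace cluster is an ``(O, S)`` pair: the object-index set ``O`` and the
attribute-index set ``S`` in which those objects group.  A clustering result is
a set of such pairs plus the noise objects assigned to none of them.  Full-space
partitioners (k-means) emit clusters whose subspace is all attributes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = ["Subspace", "as_subspace", "SubspaceCluster", "ClusteringResult"]

Subspace = tuple[int, ...]


def as_subspace(attributes: Iterable[int], d: int | None = None) -> Subspace:
    """Canonicalize an attribute collection: unique, sorted, 0-based ints."""
    attrs = tuple(sorted(set(int(a) for a in attributes)))
    if any(a < 0 for a in attrs):
        raise ValueError("attribute indices must be non-negative")
    if d is not None and any(a >= d for a in attrs):
        raise ValueError(f"attribute index out of range for d={d}")
    return attrs


@dataclass(frozen=True)
class SubspaceCluster:
    """An (objects, subspace) pair; the universal cluster representation."""

    objects: frozenset[int]
    subspace: Subspace

    def __post_init__(self) -> None:
        object.__setattr__(self, "objects", frozenset(int(o) for o in self.objects))
        object.__setattr__(self, "subspace", as_subspace(self.subspace))
        if not self.objects:
            raise ValueError("cluster object set must be non-empty")
        if not self.subspace:
            raise ValueError("cluster subspace must be non-empty")

    def sort_key(self) -> tuple:
        return (self.subspace, min(self.objects), sorted(self.objects))


@dataclass
class ClusteringResult:
    """A set of subspace clusters plus the unassigned (noise) objects."""

    clusters: list[SubspaceCluster]
    noise: frozenset[int] = frozenset()
    algorithm: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.noise = frozenset(int(o) for o in self.noise)
        self.clusters = sorted(self.clusters, key=SubspaceCluster.sort_key)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def covered_objects(self) -> frozenset[int]:
        out: set[int] = set()
        for c in self.clusters:
            out |= c.objects
        return frozenset(out)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "params": self.params,
            "clusters": [
                {"objects": sorted(c.objects), "subspace": list(c.subspace)}
                for c in self.clusters
            ],
            "noise": sorted(self.noise),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ClusteringResult":
        return cls(
            clusters=[
                SubspaceCluster(frozenset(c["objects"]), tuple(c["subspace"]))
                for c in d["clusters"]
            ],
            noise=frozenset(d.get("noise", ())),
            algorithm=d.get("algorithm", ""),
            params=d.get("params", {}),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusteringResult":
        return cls.from_dict(json.loads(Path(path).read_text()))
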