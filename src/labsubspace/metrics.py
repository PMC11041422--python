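"""Evaluation metrics for subspace clusterings against ground truth.

Two kinds of truth are supported: *hidden clusters* (planted (O, S) pairs from
the synthetic generator) and *labels* (a per-object categorical outcome such as
6-month mortality).  The five metrics mirror the standard subspace-clustering
evaluation toolkit:

- ``f1_score``     — macro F1 of the best-matching found cluster per hidden one
- ``entropy``      — size-weighted label entropy of the found clusters, in [0, 1]
- ``coverage``     — fraction of objects inside at least one cluster
- ``avg_dimensionality`` — mean subspace size over clusters
- ``outcome_accuracy``   — accuracy of majority-label cluster voting
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .results import ClusteringResult, SubspaceCluster

__all__ = [
    "GroundTruth",
    "EvalReport",
    "f1_score",
    "entropy",
    "coverage",
    "avg_dimensionality",
    "outcome_accuracy",
    "evaluate",
]


@dataclass
class GroundTruth:
    """Planted clusters and/or per-object outcome labels."""

    hidden_clusters: list[SubspaceCluster] | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.hidden_clusters is None and self.labels is None:
            raise ValueError("ground truth needs hidden clusters or labels")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)


@dataclass
class EvalReport:
    """The five metrics plus structural summaries for one algorithm run.
    ``entropy``/``avg_dim`` are None when the result has no clusters (undefined,
    reported as missing rather than zero).  ``runtime_seconds`` is informational
    only and never asserted."""

    algorithm: str
    params: dict = field(default_factory=dict)
    f1: float | None = None
    entropy: float | None = None
    coverage: float = 0.0
    n_clusters: int = 0
    avg_dim: float | None = None
    accuracy: float | None = None
    runtime_seconds: float | None = None


def _pr_f1(found: frozenset[int], hidden: frozenset[int]) -> tuple[float, float, float]:
    inter = len(found & hidden)
    p = inter / len(found) if found else 0.0
    r = inter / len(hidden) if hidden else 0.0
    f = 2 * p * r / (p + r) if (p + r) else 0.0
    return p, r, f


def f1_score(result: ClusteringResult, truth: GroundTruth) -> float:
    """Unweighted mean, over hidden clusters, of the F1 of the best-matching
    found cluster (the one maximizing the object overlap; overlap ties broken
    by higher F1)."""
    if not truth.hidden_clusters:
        raise ValueError("f1_score requires hidden clusters in the truth")
    if not result.clusters:
        return 0.0
    scores = []
    for h in truth.hidden_clusters:
        best = max(
            (len(c.objects & h.objects), _pr_f1(c.objects, h.objects)[2])
            for c in result.clusters
        )
        scores.append(best[1])
    return float(np.mean(scores))


def entropy(result: ClusteringResult, truth: GroundTruth) -> float:
    """Size-weighted mean of within-cluster label entropy, normalized by
    log2(#labels) so pure clusterings score 0 and uninformative ones 1.
    Objects appearing in several clusters count once per containing cluster."""
    if truth.labels is None:
        raise ValueError("entropy requires labels in the truth")
    if not result.clusters:
        raise ValueError("entropy undefined for a result with zero clusters")
    labels = np.asarray(truth.labels)
    n_labels = len(set(labels.tolist()))
    if n_labels < 2:
        return 0.0
    log_l = math.log2(n_labels)
    total = sum(len(c.objects) for c in result.clusters)
    e = 0.0
    for c in result.clusters:
        counts = np.array(list(Counter(labels[sorted(c.objects)].tolist()).values()))
        p = counts / counts.sum()
        h = float(-(p * np.log2(p)).sum())
        e += len(c.objects) / total * h / log_l
    return e


def coverage(result: ClusteringResult, n: int) -> float:
    """Fraction of the n objects belonging to at least one cluster."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return len(result.covered_objects()) / n


def avg_dimensionality(result: ClusteringResult) -> float:
    """Unweighted mean subspace size over clusters."""
    if not result.clusters:
        raise ValueError("avg_dimensionality undefined for zero clusters")
    return float(np.mean([len(c.subspace) for c in result.clusters]))


def _majority(values: Sequence) -> object:
    """Most common value; ties resolved to the smallest by sort order."""
    counts = Counter(values)
    top = max(counts.values())
    return sorted(v for v, c in counts.items() if c == top)[0]


def outcome_accuracy(result: ClusteringResult, truth: GroundTruth) -> float:
    """Majority-label voting accuracy.

    Each cluster maps to its majority label (within-cluster ties fall back to
    the global majority); each object is predicted by majority vote over the
    mapped labels of its containing clusters (ties and uncovered objects fall
    back to the global majority label)."""
    if truth.labels is None:
        raise ValueError("outcome_accuracy requires labels in the truth")
    labels = np.asarray(truth.labels)
    n = len(labels)
    global_majority = _majority(labels.tolist())

    cluster_label = []
    for c in result.clusters:
        counts = Counter(labels[sorted(c.objects)].tolist())
        top = max(counts.values())
        winners = [v for v, ct in counts.items() if ct == top]
        cluster_label.append(winners[0] if len(winners) == 1 else global_majority)

    votes: dict[int, list] = {}
    for lab, c in zip(cluster_label, result.clusters):
        for o in c.objects:
            votes.setdefault(o, []).append(lab)

    correct = 0
    for o in range(n):
        if o in votes:
            counts = Counter(votes[o])
            top = max(counts.values())
            winners = [v for v, ct in counts.items() if ct == top]
            pred = winners[0] if len(winners) == 1 else global_majority
        else:
            pred = global_majority
        correct += pred == labels[o]
    return correct / n


def evaluate(
    result: ClusteringResult,
    truth: GroundTruth,
    n: int,
    runtime_seconds: float | None = None,
) -> EvalReport:
    """Compute every applicable metric for one result into an :class:`EvalReport`."""
    report = EvalReport(algorithm=result.algorithm, params=dict(result.params),
                        runtime_seconds=runtime_seconds)
    report.n_clusters = result.n_clusters
    report.coverage = coverage(result, n)
    if result.clusters:
        report.avg_dim = avg_dimensionality(result)
    if truth.hidden_clusters:
        report.f1 = f1_score(result, truth)
    if truth.labels is not None:
        report.accuracy = outcome_accuracy(result, truth)
        if result.clusters:
            report.entropy = entropy(result, truth)
    return report
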