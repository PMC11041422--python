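"""Synthetic lab-panel generator with planted axis-parallel subspace clusters.

The generator emulates the statistical shape the analysis assumes in a baseline
TBI laboratory panel: 12 numeric attributes (10 chemistry/hematology labs with
published cohort means and ranges, plus the INR and aPTT coagulation tests),
uniform background over each attribute's range, planted clusters concentrated
(truncated normal) in a few *relevant* attributes and background-like in the
rest, and a binary 6-month mortality label whose rate differs inside planted
clusters — so outcome accuracy beats the majority baseline exactly when found
clusters align with outcome.

All positions and spreads for planted clusters are expressed in the generator's
normalized working domain [0, 10] and mapped affinely onto each attribute's
physical range, so the same planted geometry survives the pipeline's 0-10
min-max normalization.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .metrics import GroundTruth
from .results import Subspace, SubspaceCluster, as_subspace
from .table import LabTable

__all__ = [
    "AttributeSpec",
    "PlantedCluster",
    "SyntheticSpec",
    "default_protect_panel",
    "generate",
    "correlated_pair",
]

_DOMAIN = 10.0  # normalized working domain [0, 10]


@dataclass(frozen=True)
class AttributeSpec:
    """One lab attribute: display name, cohort mean and observed range, all in
    the lab's physical units."""

    name: str
    mean: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not self.min <= self.mean <= self.max:
            raise ValueError(f"{self.name}: need min <= mean <= max")
        if self.max <= self.min:
            raise ValueError(f"{self.name}: degenerate range")

    def to_units(self, u: np.ndarray | float) -> np.ndarray | float:
        """Map normalized-domain values [0, 10] onto [min, max]."""
        return self.min + np.asarray(u) / _DOMAIN * (self.max - self.min)


@dataclass(frozen=True)
class PlantedCluster:
    """A planted axis-parallel subspace cluster: ``size`` objects concentrated
    around ``center`` (normalized units, per relevant attribute) with standard
    deviation ``spread`` (truncated at ±3 spread), uniform elsewhere, with its
    own mortality rate."""

    size: int
    relevant: Subspace
    center: tuple[float, ...]
    spread: float
    mortality_rate: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "relevant", as_subspace(self.relevant))
        if not self.relevant:
            raise ValueError("relevant subspace must be non-empty")
        if len(self.center) != len(self.relevant):
            raise ValueError("one center coordinate per relevant attribute")
        if self.size < 1 or self.spread <= 0:
            raise ValueError("size >= 1 and spread > 0 required")
        if not 0 <= self.mortality_rate <= 1:
            raise ValueError("mortality_rate must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic table: cohort size, attribute panel,
    planted clusters, background mortality rate and RNG seed.

    ``background`` selects the background marginal: ``"uniform"`` over the
    attribute range (maximally non-clustered null) or ``"centered"`` — a
    symmetric uniform about the printed cohort mean whose half-width is capped
    by the range, so the background sample mean matches the printed mean.
    ``correlated`` lists (attr_a, attr_b, rho) Gaussian-copula couplings applied
    to background draws (uniform mode only).
    """

    n: int
    attributes: tuple[AttributeSpec, ...]
    planted: tuple[PlantedCluster, ...] = ()
    background_mortality: float = 0.14
    seed: int = 0
    background: str = "uniform"
    correlated: tuple[tuple[int, int, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(self.attributes))
        object.__setattr__(self, "planted", tuple(self.planted))
        object.__setattr__(self, "correlated", tuple(self.correlated))
        if sum(p.size for p in self.planted) > self.n:
            raise ValueError("planted sizes exceed n")
        if self.background not in ("uniform", "centered"):
            raise ValueError("background must be 'uniform' or 'centered'")
        d = len(self.attributes)
        for p in self.planted:
            if any(a >= d for a in p.relevant):
                raise ValueError("planted relevant attribute out of range")
        for a, b, rho in self.correlated:
            if not (0 <= a < d and 0 <= b < d and a != b):
                raise ValueError("invalid correlated attribute pair")
            if abs(rho) > 1:
                raise ValueError("rho must lie in [-1, 1]")


def default_protect_panel() -> list[AttributeSpec]:
    """The 12-attribute baseline panel: the ten published chemistry/hematology
    labs (cohort mean and observed range) plus the two coagulation tests.  The
    INR and aPTT ranges are this package's synthetic conventions, not published
    cohort statistics."""
    return [
        AttributeSpec("glucose", 151.6, 68.0, 554.0),        # mg/dL
        AttributeSpec("creatinine", 1.015, 0.3, 4.2),        # mg/dL
        AttributeSpec("potassium", 3.667, 1.5, 5.8),         # mmol/L
        AttributeSpec("sodium", 139.8, 125.0, 157.0),        # mmol/L
        AttributeSpec("chloride", 105.4, 88.0, 130.0),       # mmol/L
        AttributeSpec("bicarbonate", 22.77, 8.0, 34.0),      # mmol/L
        AttributeSpec("hemoglobin", 13.66, 4.9, 18.6),       # g/dL
        AttributeSpec("hematocrit", 40.31, 14.6, 54.2),      # %
        AttributeSpec("wbc", 14.85, 3.2, 41.40),             # 1e9/L
        AttributeSpec("platelets", 249.7, 51.0, 700.0),      # 1e3/mm^3
        AttributeSpec("inr", 1.2, 0.8, 6.0),                 # ratio (synthetic range)
        AttributeSpec("aptt", 28.0, 20.0, 120.0),            # s (synthetic range)
    ]


def _background_column(
    spec: SyntheticSpec, j: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Background draw for one attribute, in normalized [0, 10] units."""
    a = spec.attributes[j]
    if spec.background == "centered":
        mean_u = _DOMAIN * (a.mean - a.min) / (a.max - a.min)
        half = min(mean_u, _DOMAIN - mean_u)
        return rng.uniform(mean_u - half, mean_u + half, size=size)
    return rng.uniform(0.0, _DOMAIN, size=size)


def _truncnorm(center: float, spread: float, size: int,
               rng: np.random.Generator) -> np.ndarray:
    lo = max(0.0, center - 3.0 * spread)
    hi = min(_DOMAIN, center + 3.0 * spread)
    a, b = (lo - center) / spread, (hi - center) / spread
    return stats.truncnorm.rvs(a, b, loc=center, scale=spread, size=size,
                               random_state=rng)


def generate(spec: SyntheticSpec) -> tuple[LabTable, GroundTruth]:
    """Draw one table and its planted truth; deterministic under the spec seed.

    Planted objects occupy consecutive row blocks starting at row 0 (the truth
    records their indices, so downstream code never relies on position); the
    remaining rows are background.  Values are generated in the normalized
    [0, 10] domain and mapped onto each attribute's physical range, so the
    emitted table is in lab units.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n, len(spec.attributes)
    U = np.empty((n, d))
    for j in range(d):
        U[:, j] = _background_column(spec, j, n, rng)

    # Gaussian-copula coupling of background attribute pairs (uniform marginals)
    for a_idx, b_idx, rho in spec.correlated:
        if spec.background != "uniform":
            raise ValueError("correlated pairs require the uniform background")
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
        U[:, a_idx] = stats.norm.cdf(z1) * _DOMAIN
        U[:, b_idx] = stats.norm.cdf(z2) * _DOMAIN

    hidden: list[SubspaceCluster] = []
    mortality = (rng.uniform(size=n) < spec.background_mortality).astype(int)
    row = 0
    for p in spec.planted:
        rows = np.arange(row, row + p.size)
        for c, j in zip(p.center, p.relevant):
            U[rows, j] = _truncnorm(c, p.spread, p.size, rng)
        mortality[rows] = (rng.uniform(size=p.size) < p.mortality_rate).astype(int)
        hidden.append(SubspaceCluster(frozenset(int(r) for r in rows), p.relevant))
        row += p.size

    values = np.column_stack(
        [spec.attributes[j].to_units(U[:, j]) for j in range(d)]
    )
    table = LabTable(
        values=values,
        attribute_names=[a.name for a in spec.attributes],
        subject_ids=[f"S{i:04d}" for i in range(n)],
        mortality=mortality,
    )
    truth = GroundTruth(hidden_clusters=hidden or None, labels=mortality)
    return table, truth


def correlated_pair(
    spec: SyntheticSpec, attr_a: int, attr_b: int, rho: float
) -> SyntheticSpec:
    """Return a spec amended so background objects draw (attr_a, attr_b) from a
    Gaussian copula with correlation ``rho`` over the marginal ranges — the
    scenario in which an intrinsically coupled lab pair (hemoglobin/hematocrit)
    surfaces as a two-dimensional subspace cluster."""
    if abs(rho) > 1:
        raise ValueError("rho must lie in [-1, 1]")
    return dataclasses.replace(
        spec, correlated=spec.correlated + ((attr_a, attr_b, rho),)
    )


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Persist planted truth as JSON next to a generated CSV."""
    payload = {
        "hidden_clusters": [
            {"objects": sorted(c.objects), "subspace": list(c.subspace)}
            for c in (truth.hidden_clusters or [])
        ],
        "labels": None if truth.labels is None else
        [int(v) for v in truth.labels],
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")


def read_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    hidden = [
        SubspaceCluster(frozenset(c["objects"]), tuple(c["subspace"]))
        for c in d.get("hidden_clusters", [])
    ] or None
    labels = d.get("labels")
    return GroundTruth(
        hidden_clusters=hidden,
        labels=None if labels is None else np.asarray(labels),
    )
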