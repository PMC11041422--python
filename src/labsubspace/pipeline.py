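"""End-to-end orchestration: load or generate a table, filter and normalize,
sweep each algorithm over its parameter grid, evaluate every run, and emit a
comparison report (per-run rows plus a per-algorithm min-max summary).

All persisted artifacts (result JSONs, report and summary CSVs) are written
deterministically — runtimes are logged, never written — so a rerun with the
same config and seed reproduces the output byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cells import CellParams, mineclus
from .density import DensityParams, subclu
from .metrics import EvalReport, GroundTruth, evaluate
from .projected import ProclusParams, kmeans, proclus
from .results import ClusteringResult
from .synthetic import SyntheticSpec, default_protect_panel, generate, read_truth
from .table import (
    InclusionCriteria,
    LabTable,
    ParamGrid,
    apply_inclusion_filter,
    load_table,
    make_param_grid,
    normalize,
)

__all__ = ["RunConfig", "run_pipeline", "load_config", "DEFAULT_MINPTS_GRID",
           "DEFAULT_EPS_GRID"]

log = logging.getLogger("labsubspace")

# The study protocol's density grids: MinPts 8..128 in steps of 30 (five
# values), eps 0.01..0.25 in steps of 0.03 (nine values).
DEFAULT_MINPTS_GRID = ParamGrid(8, 30, 128)
DEFAULT_EPS_GRID = ParamGrid(0.01, 0.03, 0.25)


@dataclass
class RunConfig:
    """One pipeline run: input source, algorithms, grids, output directory."""

    input_csv: str | None = None
    truth_json: str | None = None
    synthetic: SyntheticSpec | None = None
    algorithms: list[str] = field(
        default_factory=lambda: ["subclu", "mineclus", "proclus", "kmeans"]
    )
    normalize_lo: float = 0.0
    normalize_hi: float = 10.0
    inclusion: InclusionCriteria | None = None
    minpts_grid: ParamGrid = DEFAULT_MINPTS_GRID
    eps_grid: ParamGrid = DEFAULT_EPS_GRID
    subclu_max_dim: int | None = None
    cell_w: list[float] = field(default_factory=lambda: [1.0])
    cell_tau_fraction: float = 0.05
    cell_beta: float = 0.25
    proclus_k: list[int] = field(default_factory=lambda: [8, 16, 32])
    proclus_l: int = 3
    kmeans_k: list[int] = field(default_factory=lambda: [2, 8, 16, 32])
    outdir: str = "runs"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.algorithms:
            raise ValueError("at least one algorithm required")
        unknown = set(self.algorithms) - {"subclu", "mineclus", "proclus", "kmeans"}
        if unknown:
            raise ValueError(f"unknown algorithm(s): {sorted(unknown)}")
        if self.input_csv is None and self.synthetic is None:
            raise ValueError("config needs an input CSV or a synthetic spec")


def _resolve_input(config: RunConfig) -> tuple[LabTable, GroundTruth | None]:
    if config.synthetic is not None:
        table, truth = generate(config.synthetic)
        return table, truth
    table = load_table(config.input_csv)
    truth = None
    if config.truth_json:
        truth = read_truth(config.truth_json)
    elif table.mortality is not None:
        truth = GroundTruth(labels=table.mortality)
    return table, truth


def _grid_points(config: RunConfig, n: int) -> list[tuple[str, dict]]:
    """Expand every algorithm's grid into (algorithm, params) runs, in report order."""
    runs: list[tuple[str, dict]] = []
    for alg in config.algorithms:
        if alg == "subclu":
            for minpts in make_param_grid(config.minpts_grid):
                for eps in make_param_grid(config.eps_grid):
                    runs.append(("subclu", {"eps": float(eps),
                                            "minpts": int(round(minpts))}))
        elif alg == "mineclus":
            tau = max(1, int(np.ceil(config.cell_tau_fraction * n)))
            for w in config.cell_w:
                runs.append(("mineclus", {"w": float(w), "tau": tau,
                                          "beta": config.cell_beta}))
        elif alg == "proclus":
            for k in config.proclus_k:
                runs.append(("proclus", {"k": int(k), "l": config.proclus_l}))
        elif alg == "kmeans":
            for k in config.kmeans_k:
                runs.append(("kmeans", {"k": int(k)}))
    return runs


def _run_one(alg: str, params: dict, table: LabTable, config: RunConfig,
             v: float) -> ClusteringResult:
    if alg == "subclu":
        return subclu(table, DensityParams(params["eps"], params["minpts"]),
                      max_dim=config.subclu_max_dim)
    if alg == "mineclus":
        return mineclus(table, CellParams(w=params["w"], tau=params["tau"],
                                          beta=params["beta"], seed=config.seed,
                                          v=v))
    if alg == "proclus":
        res, _ = proclus(table, ProclusParams(k=params["k"], l=params["l"],
                                              seed=config.seed))
        return res
    if alg == "kmeans":
        return kmeans(table, k=params["k"], seed=config.seed)
    raise ValueError(f"unknown algorithm {alg!r}")


_METRIC_COLS = ["f1", "entropy", "coverage", "n_clusters", "avg_dim", "accuracy"]


def _report_frame(reports: list[EvalReport]) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(reports):
        row = {"run": i, "algorithm": r.algorithm,
               "params": ";".join(f"{k}={v}" for k, v in sorted(r.params.items())
                                  if k not in ("medoids", "wcss", "seed",
                                               "n_restarts", "metric",
                                               "max_dim", "_failed"))}
        for c in _METRIC_COLS:
            row[c] = getattr(r, c)
        row["status"] = "ok" if r.params.get("_failed") is None else "failed"
        rows.append(row)
    return pd.DataFrame(rows)


def _summary_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Per-algorithm min-max of each metric — the comparison-table shape."""
    rows = []
    for alg, grp in df[df.status == "ok"].groupby("algorithm", sort=True):
        row = {"algorithm": alg}
        for c in _METRIC_COLS:
            vals = grp[c].dropna()
            row[f"{c}_min"] = vals.min() if len(vals) else None
            row[f"{c}_max"] = vals.max() if len(vals) else None
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> list[EvalReport]:
    """Execute the full workflow and persist results under ``config.outdir``.

    Per grid point: run the algorithm, evaluate against the available truth,
    persist the clustering as JSON.  A grid point that raises is recorded as a
    failed report, not a pipeline abort.  Writes ``report.csv`` (one row per
    run) and ``summary.csv`` (per-algorithm min-max of each metric; every
    summary value is attained by some individual run).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth = _resolve_input(config)
    log.info("input: %d subjects x %d attributes", table.n_subjects,
             table.n_attributes)
    if config.inclusion is not None:
        table, excluded = apply_inclusion_filter(table, config.inclusion)
        log.info("inclusion filter kept %d subjects (excluded: %s)",
                 table.n_subjects, excluded)
    table = normalize(table, config.normalize_lo, config.normalize_hi)
    n = table.n_subjects

    reports: list[EvalReport] = []
    for i, (alg, params) in enumerate(_grid_points(config, n)):
        t0 = time.perf_counter()
        try:
            result = _run_one(alg, params, table, config, v=config.normalize_hi)
            elapsed = time.perf_counter() - t0
            if truth is not None:
                rep = evaluate(result, truth, n, runtime_seconds=elapsed)
            else:
                rep = EvalReport(algorithm=alg, params=dict(params),
                                 n_clusters=result.n_clusters,
                                 coverage=len(result.covered_objects()) / n,
                                 runtime_seconds=elapsed)
            rep.params = {**params, **{k: v for k, v in rep.params.items()
                                       if k not in params}}
            result.to_json(outdir / f"result_{i:03d}_{alg}.json")
            log.info("run %d %s %s: %d clusters in %.2fs", i, alg, params,
                     result.n_clusters, elapsed)
        except Exception as exc:  # partial-failure policy: record, continue
            log.warning("run %d %s %s failed: %s", i, alg, params, exc)
            rep = EvalReport(algorithm=alg, params={**params, "_failed": str(exc)})
        reports.append(rep)

    df = _report_frame(reports)
    df.to_csv(outdir / "report.csv", index=False, float_format="%.6f")
    _summary_frame(df).to_csv(outdir / "summary.csv", index=False,
                              float_format="%.6f")
    return reports


def _spec_from_dict(d: dict) -> SyntheticSpec:
    from .synthetic import AttributeSpec, PlantedCluster

    attrs = d.get("attributes")
    if attrs in (None, "protect_panel"):
        attributes = tuple(default_protect_panel())
    else:
        attributes = tuple(AttributeSpec(**a) for a in attrs)
    planted = tuple(
        PlantedCluster(size=p["size"], relevant=tuple(p["relevant"]),
                       center=tuple(p["center"]), spread=p["spread"],
                       mortality_rate=p.get("mortality_rate", 0.5))
        for p in d.get("planted", [])
    )
    return SyntheticSpec(
        n=d["n"], attributes=attributes, planted=planted,
        background_mortality=d.get("background_mortality", 0.14),
        seed=d.get("seed", 0), background=d.get("background", "uniform"),
        correlated=tuple(tuple(c) for c in d.get("correlated", [])),
    )


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a flat, namespaced YAML config file into a :class:`RunConfig`.

    Recognized keys (all optional unless noted): ``input.csv``, ``input.truth``,
    ``synthetic`` (mapping: n, attributes | "protect_panel", planted, seed, ...),
    ``algorithms`` (list), ``normalize.lo``, ``normalize.hi``,
    ``inclusion.min_survival_days``, ``inclusion.require_baseline_labs``,
    ``density.minpts`` / ``density.eps`` (mappings start/step/max),
    ``density.max_dim``, ``cell.w`` (list), ``cell.tau_fraction``, ``cell.beta``,
    ``proclus.k`` (list), ``proclus.l``, ``kmeans.k`` (list), ``outdir``, ``seed``.
    Keyword overrides win over file values.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}

    def grid(key: str, default: ParamGrid) -> ParamGrid:
        g = raw.get(key)
        return default if g is None else ParamGrid(g["start"], g["step"], g["max"])

    kwargs: dict = dict(
        input_csv=raw.get("input.csv"),
        truth_json=raw.get("input.truth"),
        synthetic=(_spec_from_dict(raw["synthetic"])
                   if "synthetic" in raw else None),
        normalize_lo=raw.get("normalize.lo", 0.0),
        normalize_hi=raw.get("normalize.hi", 10.0),
        minpts_grid=grid("density.minpts", DEFAULT_MINPTS_GRID),
        eps_grid=grid("density.eps", DEFAULT_EPS_GRID),
        subclu_max_dim=raw.get("density.max_dim"),
        cell_w=raw.get("cell.w", [1.0]),
        cell_tau_fraction=raw.get("cell.tau_fraction", 0.05),
        cell_beta=raw.get("cell.beta", 0.25),
        proclus_k=raw.get("proclus.k", [8, 16, 32]),
        proclus_l=raw.get("proclus.l", 3),
        kmeans_k=raw.get("kmeans.k", [2, 8, 16, 32]),
        outdir=raw.get("outdir", "runs"),
        seed=raw.get("seed", 0),
    )
    if "algorithms" in raw:
        kwargs["algorithms"] = list(raw["algorithms"])
    if any(k.startswith("inclusion.") for k in raw):
        kwargs["inclusion"] = InclusionCriteria(
            min_survival_days=raw.get("inclusion.min_survival_days", 3),
            require_baseline_labs=raw.get("inclusion.require_baseline_labs", True),
        )
    kwargs.update(overrides)
    return RunConfig(**kwargs)
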