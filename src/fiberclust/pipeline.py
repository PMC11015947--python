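"""End-to-end orchestration: classify -> null -> SD_UG -> clusters -> cohort stats.

One :class:`AnalysisConfig` carries every tunable (neighbor order k,
simulation count S, SD threshold, minimum cluster size, diameter bands,
grid shape, master seed).  Stage seeds are spawned deterministically from
the master seed via ``numpy.random.SeedSequence(master).spawn``, keyed by
(root, fascicle, scope, stage) order, so a whole run is reproducible and
individual stages can be re-run in isolation.

Scopes whose fiber count cannot support the analysis (n <= k) are recorded
as skips with a reason, never crashes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .classify import ClassBands, assign_classes, class_proportions
from .cluster import ClusterParams, ClusteringResult, delineate
from .exceptions import EmptyResultError, FiberclustError
from .geometry import Fascicle, FiberClass, Root
from .null import simulate_null
from .stats import (
    SdugResult,
    correlate,
    grid_intensity,
    group_compare,
    sdug,
    weighted_root_sdug,
)

__all__ = ["AnalysisConfig", "RootSummary", "run_root", "run_cohort"]

SCHEMA_VERSION = 1
_SCOPES = ("whole", "PPN", "GAMMA", "ALPHA")


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunables of an end-to-end run."""

    k: int = 50
    n_simulations: int = 1000
    threshold_sd: float = -4.0
    min_size: int = 4
    calibration: str = "knn-mean"
    ppn_max: float = 4.0
    gamma_max: float = 10.0
    grid_nx: int = 6
    grid_ny: int = 6
    ppn_split: int = 50
    seed: int = 0
    scopes: tuple[str, ...] = _SCOPES

    @property
    def bands(self) -> ClassBands:
        return ClassBands(ppn_max=self.ppn_max, gamma_max=self.gamma_max)

    @property
    def cluster_params(self) -> ClusterParams:
        return ClusterParams(
            min_size=self.min_size, threshold_sd=self.threshold_sd,
            calibration=self.calibration, k_null=self.k,
        )

    @classmethod
    def from_toml(cls, path: str | Path) -> "AnalysisConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data = data.get("fiberclust", data)
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        if "scopes" in kwargs:
            kwargs["scopes"] = tuple(kwargs["scopes"])
        return cls(**kwargs)


@dataclass
class RootSummary:
    """Per-root results: the rows behind cohort-level figures and tables."""

    root_id: str
    animal_id: str
    n_fibers: int
    class_counts: dict[str, int]
    class_proportions: dict[str, float]
    sdug_by_scope: dict[str, SdugResult | None]
    skip_reasons: dict[str, str]
    clustering_by_scope: dict[str, ClusteringResult | None]
    grid_counts: list[list[int]]
    provenance: dict = field(default_factory=dict)

    @property
    def ppn_count(self) -> int:
        return self.class_counts.get("PPN", 0)

    def sd_ug(self, scope: str = "whole") -> float | None:
        res = self.sdug_by_scope.get(scope)
        return None if res is None else res.sd_ug

    def to_dict(self) -> dict:
        def sdug_obj(r: SdugResult | None):
            if r is None:
                return None
            return {
                "d_g": r.d_g, "sd_ug": r.sd_ug, "k": r.k, "n": r.n,
                "D_U": r.null.D_U, "sigma_U": r.null.sigma_U, "scope": r.scope,
                "level": r.level,
            }

        def clust_obj(c: ClusteringResult | None):
            if c is None:
                return None
            return {
                "n_clusters": c.n_clusters,
                "n_noise": c.n_noise,
                "eps_used": c.eps_used,
                "labels": c.labels.tolist(),
            }

        return {
            "schema_version": SCHEMA_VERSION,
            "root_id": self.root_id,
            "animal_id": self.animal_id,
            "n_fibers": self.n_fibers,
            "class_counts": self.class_counts,
            "class_proportions": self.class_proportions,
            "sdug": {s: sdug_obj(r) for s, r in self.sdug_by_scope.items()},
            "skips": self.skip_reasons,
            "clusters": {s: clust_obj(c) for s, c in self.clustering_by_scope.items()},
            "grid_counts": self.grid_counts,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def run_root(root: Root, config: AnalysisConfig | None = None) -> RootSummary:
    """Run the full analysis for one root.

    Per fascicle and scope: classify fibers, simulate the uniform null at
    the in-scope n, compute SD_UG, and delineate clusters; fascicle values
    combine into root-level SD_UG by fiber-count weighting.  Deterministic
    given ``config.seed``.
    """
    config = config or AnalysisConfig()
    master = np.random.SeedSequence(config.seed)
    for fas in root.fascicles:
        assign_classes(fas.fibers, config.bands)
    try:
        props = class_proportions(root.fascicles)
    except EmptyResultError:
        props = {}
    counts = {
        c.value: sum(1 for f in root.all_fibers() if f.fiber_class == c)
        for c in (FiberClass.PPN, FiberClass.GAMMA, FiberClass.ALPHA, FiberClass.UNASSIGNED)
    }

    sdug_by_scope: dict[str, SdugResult | None] = {}
    clustering_by_scope: dict[str, ClusteringResult | None] = {}
    skips: dict[str, str] = {}
    stage_streams = master.spawn(len(config.scopes) * len(root.fascicles) * 2)
    stream_idx = 0

    for scope in config.scopes:
        fas_results: list[SdugResult] = []
        fas_clusters: list[ClusteringResult] = []
        for fas in root.fascicles:
            n_scope = len(fas.select(scope))
            sdug_stream = stage_streams[stream_idx]
            clus_stream = stage_streams[stream_idx + 1]
            stream_idx += 2
            if n_scope <= config.k:
                skips.setdefault(scope, f"n={n_scope} <= k={config.k} in fascicle {fas.fascicle_id}")
                continue
            null = simulate_null(
                fas.region, n=n_scope, k=config.k,
                n_simulations=config.n_simulations, random_state=sdug_stream,
            )
            fas_results.append(sdug(fas, null, scope=scope))
            params = config.cluster_params
            if params.calibration == "knn-mean":
                clus_null = null  # same k: reuse instead of re-simulating
            else:
                clus_null = simulate_null(
                    fas.region, n=n_scope, k=params.null_k,
                    n_simulations=config.n_simulations, random_state=clus_stream,
                )
            fas_clusters.append(delineate(fas, scope=scope, params=params, null=clus_null))
        if not fas_results:
            sdug_by_scope[scope] = None
            clustering_by_scope[scope] = None
            continue
        if len(fas_results) == 1:
            sdug_by_scope[scope] = fas_results[0]
        else:
            combined = weighted_root_sdug(fas_results)
            ref = fas_results[0]
            sdug_by_scope[scope] = SdugResult(
                d_g=float("nan"), sd_ug=combined, k=ref.k,
                n=sum(r.n for r in fas_results), null=ref.null,
                scope=scope, level="root",
            )
        clustering_by_scope[scope] = fas_clusters[0] if len(fas_clusters) == 1 else None

    if all(v is None for v in sdug_by_scope.values()):
        raise EmptyResultError(f"root {root.root_id!r}: every scope was skipped: {skips}")

    grid = grid_intensity(root.fascicles[0], nx=config.grid_nx, ny=config.grid_ny)
    return RootSummary(
        root_id=root.root_id,
        animal_id=root.animal_id,
        n_fibers=root.n_fibers,
        class_counts=counts,
        class_proportions=props,
        sdug_by_scope=sdug_by_scope,
        skip_reasons=skips,
        clustering_by_scope=clustering_by_scope,
        grid_counts=grid.counts.tolist(),
        provenance={
            "seed": config.seed,
            "k": config.k,
            "n_simulations": config.n_simulations,
            "threshold_sd": config.threshold_sd,
            "min_size": config.min_size,
            "calibration": config.calibration,
            "bands": [config.ppn_max, config.gamma_max],
            "grid": [config.grid_nx, config.grid_ny],
            "software_version": __version__,
            "config": asdict(config),
        },
    )


def run_cohort(
    summaries: list[RootSummary],
    ppn_split: int = 50,
    groups: dict[str, list[str]] | None = None,
) -> dict:
    """Cohort-level table and statistics over per-root summaries.

    Returns a dict with a long-format table (one row per root and scope),
    Pearson r / R^2 of PPN fiber count against whole-root SD_UG — overall
    and within the two subsets split at ``ppn_split`` PPN fibers — and
    optional pairwise Mann-Whitney comparisons between named groups of
    root ids.  Subsets with fewer than 3 roots skip correlation with a
    recorded reason.
    """
    if not summaries:
        raise EmptyResultError("run_cohort needs at least one root summary")
    rows = []
    for s in summaries:
        for scope, res in s.sdug_by_scope.items():
            rows.append(
                {
                    "root_id": s.root_id,
                    "animal_id": s.animal_id,
                    "scope": scope,
                    "n": None if res is None else res.n,
                    "sd_ug": None if res is None else res.sd_ug,
                    "ppn_count": s.ppn_count,
                    "ppn_frac": s.class_proportions.get("PPN"),
                }
            )
    table = pd.DataFrame(rows)

    whole = table[(table.scope == "whole") & table.sd_ug.notna()]
    correlations: dict[str, dict | str] = {}

    def corr(name: str, sub: pd.DataFrame) -> None:
        if len(sub) < 3:
            correlations[name] = f"skipped: only {len(sub)} roots (< 3)"
            return
        try:
            correlations[name] = correlate(sub.ppn_count.to_numpy(), sub.sd_ug.to_numpy())
        except ValueError as exc:
            correlations[name] = f"skipped: {exc}"

    corr("all", whole)
    corr(f"lt{ppn_split}", whole[whole.ppn_count < ppn_split])
    corr(f"ge{ppn_split}", whole[whole.ppn_count >= ppn_split])

    comparisons: dict[str, dict] = {}
    if groups:
        names = sorted(groups)
        by_root = whole.set_index("root_id").sd_ug
        for i, ga in enumerate(names):
            for gb in names[i + 1 :]:
                va = by_root.reindex(groups[ga]).dropna().to_numpy()
                vb = by_root.reindex(groups[gb]).dropna().to_numpy()
                if va.size and vb.size:
                    comparisons[f"{ga}_vs_{gb}"] = group_compare(va, vb)

    return {
        "table": table,
        "correlations": correlations,
        "comparisons": comparisons,
        "ppn_split": ppn_split,
    }
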