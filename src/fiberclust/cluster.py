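"""Nonbinary nerve-fiber cluster delineation via OPTICS.

Clusters are delineated in three steps:

1.  OPTICS ordering (Ankerst et al. 1999): each fiber gets a core distance
    (distance to its (min_pts - 1)th other fiber) and a reachability
    distance; fibers are visited by a priority queue of smallest
    reachability, ties broken by ascending input index, which makes runs
    deterministic.
2.  The reachability cut eps is calibrated in SD units of the Monte-Carlo
    uniform null:  eps = D_U + t * sigma_U  with t <= 0 typical.  t = 0
    cuts at the null mean distance itself; more negative t demands fibers
    sit further below what uniform placement would produce.
3.  A flat eps-cut (DBSCAN-equivalent) extracts clusters from the ordering,
    and runs shorter than ``min_size`` are relabeled noise.

Two calibrations of the null are offered.  ``"knn-mean"`` (the default)
uses the same neighbor order as the SD_UG index (k_null, default 50), so
eps lives on the mean-50NN scale: permissive at t = 0 — a dense pattern
collapses into a single all-inclusive cluster — and progressively strict
as t decreases.  ``"scale-matched"`` simulates the null at
k = min_size - 1, the same order as the OPTICS core distances, so the cut
compares like with like; this is the mode to use when the goal is to
recover compact planted clusters against a diffuse background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .exceptions import InfeasibleThresholdError, InsufficientPointsError
from .geometry import Fascicle
from .null import NullDistribution, simulate_null

__all__ = [
    "NOISE",
    "ClusterParams",
    "ClusteringResult",
    "OpticsOrdering",
    "optics_ordering",
    "eps_from_sd",
    "extract_clusters",
    "delineate",
    "threshold_sweep",
    "NullCalibratedOPTICS",
]

#: label assigned to fibers not in any cluster
NOISE = -1


@dataclass(frozen=True)
class ClusterParams:
    """User-facing cluster criteria.

    min_size : minimum fibers per cluster (and OPTICS min_pts), >= 2.
    threshold_sd : cut position in SD units of the null; <= 0 typical.
    k_null : neighbor order of the calibrating null for "knn-mean".
    calibration : "knn-mean" or "scale-matched" (null at k = min_size - 1).
    """

    min_size: int = 4
    threshold_sd: float = -4.0
    k_null: int = 50
    calibration: str = "knn-mean"

    def __post_init__(self) -> None:
        if self.min_size < 2:
            raise ValueError(f"min_size must be >= 2, got {self.min_size}")
        if self.calibration not in ("knn-mean", "scale-matched"):
            raise ValueError(f"unknown calibration {self.calibration!r}")

    @property
    def null_k(self) -> int:
        """Neighbor order at which the calibrating null is simulated."""
        return self.k_null if self.calibration == "knn-mean" else self.min_size - 1


class OpticsOrdering(NamedTuple):
    """Raw OPTICS output: visit order, per-point reachability/core distances."""

    ordering: np.ndarray  # visit order (point indices)
    reachability: np.ndarray  # per-point, +inf for each component seed
    core_distances: np.ndarray  # per-point distance to (min_pts-1)th other


@dataclass(frozen=True)
class ClusteringResult:
    """Flat clusters from an eps-cut of the OPTICS ordering.

    ``labels[i]`` is the cluster id of fiber i, or ``NOISE`` (-1).  Every
    cluster has at least ``params.min_size`` members.
    """

    labels: np.ndarray
    eps_used: float
    params: ClusterParams
    ordering: np.ndarray
    reachability: np.ndarray
    core_distances: np.ndarray
    null: NullDistribution | None = None
    n_clusters: int = field(init=False)

    def __post_init__(self) -> None:
        ids = np.unique(self.labels[self.labels != NOISE])
        object.__setattr__(self, "n_clusters", int(ids.size))

    @property
    def n_noise(self) -> int:
        return int(np.sum(self.labels == NOISE))

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


def optics_ordering(
    points: np.ndarray, min_pts: int, max_eps: float = np.inf
) -> OpticsOrdering:
    """Compute the OPTICS visit order and reachability profile.

    Semantics follow Ankerst et al. (1999): the core distance of p is the
    distance to its (min_pts - 1)th other point (undefined, +inf, if that
    exceeds ``max_eps``); the reachability of q from a core point p is
    max(core(p), dist(p, q)).  Points are visited in order of smallest
    current reachability with ties broken by ascending input index; the
    first point of each connected component keeps reachability +inf.

    O(n^2) time and memory — ample for section-scale fiber counts.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if min_pts < 2:
        raise ValueError(f"min_pts must be >= 2, got {min_pts}")
    if n < min_pts:
        raise InsufficientPointsError(
            f"OPTICS needs at least min_pts={min_pts} points, got {n}"
        )
    diff = points[:, None, :] - points[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    # distance to the (min_pts-1)th other point == index min_pts-1 among others,
    # i.e. index min_pts-1 in the row sorted with self at position 0
    core = np.partition(dist, min_pts - 1, axis=1)[:, min_pts - 1]
    core_eff = np.where(core <= max_eps, core, np.inf)

    reach = np.full(n, np.inf)
    processed = np.zeros(n, dtype=bool)
    order = np.empty(n, dtype=int)
    for step in range(n):
        masked = np.where(processed, np.inf, reach)
        # np.argmin returns the first (= lowest-index) minimum: the tie rule
        p = int(np.argmin(masked))
        if not np.isfinite(masked[p]):
            # new component: seed is the lowest-index unprocessed point
            p = int(np.flatnonzero(~processed)[0])
        order[step] = p
        processed[p] = True
        if np.isfinite(core_eff[p]):
            new_reach = np.maximum(core_eff[p], dist[p])
            within = dist[p] <= max_eps
            upd = (~processed) & within & (new_reach < reach)
            reach[upd] = new_reach[upd]
    return OpticsOrdering(ordering=order, reachability=reach, core_distances=core)


def eps_from_sd(null: NullDistribution, threshold_sd: float) -> float:
    """Map an SD-unit threshold to a reachability cut (µm).

    eps = D_U + threshold_sd * sigma_U.

    Raises
    ------
    InfeasibleThresholdError
        If eps would be <= 0; the error reports the minimum feasible
        threshold -D_U / sigma_U.
    """
    eps = null.D_U + threshold_sd * null.sigma_U
    if eps <= 0:
        t_min = -null.D_U / null.sigma_U
        raise InfeasibleThresholdError(
            f"threshold {threshold_sd:g} SD gives eps = {eps:g} <= 0 for this null "
            f"(D_U={null.D_U:g}, sigma_U={null.sigma_U:g}); "
            f"the minimum feasible threshold is {t_min:g}",
            min_feasible_sd=t_min,
        )
    return float(eps)


def extract_clusters(
    ordering: np.ndarray,
    reachability: np.ndarray,
    core_distances: np.ndarray,
    eps_used: float,
    min_size: int,
) -> np.ndarray:
    """Flat eps-cut extraction (DBSCAN-equivalent) from an OPTICS ordering.

    Scanning the visit order: a point with reachability <= eps joins the
    current cluster; a point with reachability > eps opens a new cluster
    if its core distance is <= eps and is noise otherwise.  Runs shorter
    than ``min_size`` are relabeled noise.  Returns per-point labels.
    """
    n = len(ordering)
    labels = np.full(n, NOISE, dtype=int)
    current = NOISE
    next_id = 0
    for p in ordering:
        if reachability[p] > eps_used:
            if core_distances[p] <= eps_used:
                current = next_id
                next_id += 1
                labels[p] = current
            else:
                current = NOISE
        else:
            labels[p] = current
    # enforce the minimum cluster size, then compact the ids
    kept: dict[int, int] = {}
    for cid in range(next_id):
        members = np.flatnonzero(labels == cid)
        if members.size < min_size:
            labels[members] = NOISE
        else:
            kept[cid] = len(kept)
    labels = np.array([kept.get(l, NOISE) if l != NOISE else NOISE for l in labels])
    return labels


def delineate(
    fascicle: Fascicle,
    scope: str | None = None,
    params: ClusterParams | None = None,
    null: NullDistribution | None = None,
    n_simulations: int = 1000,
    random_state=None,
) -> ClusteringResult:
    """End-to-end cluster delineation for the in-scope fibers of a fascicle.

    Simulates the calibrating null for the in-scope n (unless supplied),
    converts ``params.threshold_sd`` into a reachability cut, orders the
    centroids with OPTICS (min_pts = min_size) and extracts flat clusters.
    """
    params = params or ClusterParams()
    pts = fascicle.coords(scope)
    n = pts.shape[0]
    k_cal = params.null_k
    if n < max(params.min_size, k_cal + 1):
        raise InsufficientPointsError(
            f"scope {scope or 'whole'!r}: n={n} fibers, need at least "
            f"max(min_size, k_null+1) = {max(params.min_size, k_cal + 1)}"
        )
    if null is None:
        null = simulate_null(
            fascicle.region, n=n, k=k_cal, n_simulations=n_simulations,
            random_state=random_state,
        )
    eps = eps_from_sd(null, params.threshold_sd)
    opt = optics_ordering(pts, min_pts=params.min_size)
    labels = extract_clusters(
        opt.ordering, opt.reachability, opt.core_distances, eps, params.min_size
    )
    return ClusteringResult(
        labels=labels,
        eps_used=eps,
        params=params,
        ordering=opt.ordering,
        reachability=opt.reachability,
        core_distances=opt.core_distances,
        null=null,
    )


def threshold_sweep(
    fascicle: Fascicle,
    thresholds,
    scope: str | None = None,
    params: ClusterParams | None = None,
    null: NullDistribution | None = None,
    n_simulations: int = 1000,
    random_state=None,
) -> dict[float, ClusteringResult]:
    """Delineate at several SD thresholds, reusing one null and one ordering.

    The OPTICS ordering depends only on min_pts, so sweeping the threshold
    is a cheap re-cut of the same reachability profile.
    """
    params = params or ClusterParams()
    pts = fascicle.coords(scope)
    if null is None:
        null = simulate_null(
            fascicle.region, n=pts.shape[0], k=params.null_k,
            n_simulations=n_simulations, random_state=random_state,
        )
    opt = optics_ordering(pts, min_pts=params.min_size)
    out: dict[float, ClusteringResult] = {}
    for t in thresholds:
        p_t = ClusterParams(
            min_size=params.min_size, threshold_sd=float(t),
            k_null=params.k_null, calibration=params.calibration,
        )
        eps = eps_from_sd(null, t)
        labels = extract_clusters(
            opt.ordering, opt.reachability, opt.core_distances, eps, params.min_size
        )
        out[float(t)] = ClusteringResult(
            labels=labels, eps_used=eps, params=p_t, ordering=opt.ordering,
            reachability=opt.reachability, core_distances=opt.core_distances, null=null,
        )
    return out


class NullCalibratedOPTICS(ClusterMixin, BaseEstimator):
    """OPTICS clusterer with a reachability cut in SD units of the CSR null.

    scikit-learn style: ``fit(X, region=...)`` on an (n, 2) centroid array
    sets ``labels_`` (noise = -1); composes with sklearn metrics and
    pipelines via ``fit_predict``.

    Parameters
    ----------
    min_size : int
        Minimum fibers per cluster and OPTICS min_pts.
    threshold_sd : float
        Cut position in null SD units (0 = at the null mean; negative =
        stricter).
    k_null : int
        Neighbor order of the calibrating null for ``calibration="knn-mean"``.
    calibration : {"knn-mean", "scale-matched"}
        Scale of the cut: the SD_UG neighbor order (permissive) or the
        OPTICS core-distance order k = min_size - 1 (cluster recovery).
    n_simulations : int
        Monte-Carlo placements for the null.
    random_state : int or None

    Attributes
    ----------
    labels_ : (n,) int array
        Cluster ids, noise = -1.
    n_clusters_ : int
    eps_used_ : float
        The reachability cut in µm.
    ordering_, reachability_, core_distances_ : arrays
        The underlying OPTICS profile.
    null_ : NullDistribution
    """

    def __init__(
        self,
        min_size: int = 4,
        threshold_sd: float = -4.0,
        k_null: int = 50,
        calibration: str = "knn-mean",
        n_simulations: int = 1000,
        random_state=None,
    ):
        self.min_size = min_size
        self.threshold_sd = threshold_sd
        self.k_null = k_null
        self.calibration = calibration
        self.n_simulations = n_simulations
        self.random_state = random_state

    def fit(self, X, y=None, *, region=None, null: NullDistribution | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(f"X must be an (n, 2) coordinate array, got shape {X.shape}")
        params = ClusterParams(
            min_size=self.min_size, threshold_sd=self.threshold_sd,
            k_null=self.k_null, calibration=self.calibration,
        )
        if null is None:
            if region is None:
                raise ValueError("fit requires either region=... or a precomputed null=...")
            null = simulate_null(
                region, n=X.shape[0], k=params.null_k,
                n_simulations=self.n_simulations, random_state=self.random_state,
            )
        eps = eps_from_sd(null, self.threshold_sd)
        opt = optics_ordering(X, min_pts=self.min_size)
        labels = extract_clusters(
            opt.ordering, opt.reachability, opt.core_distances, eps, self.min_size
        )
        self.n_features_in_ = 2
        self.labels_ = labels
        self.n_clusters_ = int(np.unique(labels[labels != NOISE]).size)
        self.eps_used_ = eps
        self.ordering_ = opt.ordering
        self.reachability_ = opt.reachability
        self.core_distances_ = opt.core_distances
        self.null_ = null
        return self
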