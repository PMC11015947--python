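"""Spatial statistics: the SD_UG clustering index and its diagnostics.

The central quantity is the standardized clustering index

    SD_UG = (D_G - D_U) / sigma_U

where D_G is the observed mean kth-nearest-neighbor distance, and D_U and
sigma_U come from the Monte-Carlo uniform null for the same region, n and
k.  Negative values mean the observed fibers sit closer together than
uniform placements (clustered); positive values mean dispersion.  Because
the null shares the region geometry and the fiber count, SD_UG is
comparable across roots of different size, shape, and fiber number, and is
invariant under rigid translation and uniform scaling of the section.

For multi-fascicle roots the index is computed per fascicle and combined
by fiber-count weighting:  SD_UG(root) = sum_k n_k SD_UG^k / sum_k n_k.

Diagnostics: a normalized Ripley L-function (L(r) - r, flat under CSR)
with a pointwise Monte-Carlo envelope guides the choice of the neighbor
order k, and a coarse grid intensity map summarizes where fibers sit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .exceptions import ConsistencyError, InsufficientPointsError
from .geometry import Fascicle, Region
from .null import NullDistribution, knn_mean_distance, sample_uniform_points, simulate_null

__all__ = [
    "SdugResult",
    "LCurve",
    "GridIntensity",
    "ground_truth_distance",
    "sdug",
    "weighted_root_sdug",
    "normalized_l_function",
    "grid_intensity",
    "group_compare",
    "correlate",
    "ClusteringIndex",
]


@dataclass(frozen=True)
class SdugResult:
    """One SD_UG evaluation: observed D_G standardized against a null."""

    d_g: float  # observed mean kNN distance (µm)
    sd_ug: float  # standardized index, dimensionless
    k: int
    n: int
    null: NullDistribution
    scope: str = "whole"  # whole | PPN | GAMMA | ALPHA
    level: str = "fascicle"  # fascicle | root

    @property
    def clustered(self) -> bool:
        """Negative index: fibers closer than uniform placements."""
        return self.sd_ug < 0


@dataclass(frozen=True)
class LCurve:
    """Normalized L-function with Monte-Carlo envelope and k markers.

    ``l_norm(r) = L(r) - r`` where ``L(r) = sqrt(K(r)/pi)``; zero in
    expectation under CSR, positive where circles of radius r capture more
    fibers than a uniform pattern would give.  ``k_markers`` maps neighbor
    order to the null-mean kNN radius, locating candidate k choices on the
    radius axis.
    """

    radii: np.ndarray
    l_norm: np.ndarray
    envelope_lo: np.ndarray
    envelope_hi: np.ndarray
    k_markers: dict[int, float]


@dataclass(frozen=True)
class GridIntensity:
    """Centroid counts over an nx-by-ny partition of the region bbox.

    ``counts[iy, ix]`` is the number of centroids in the half-open cell
    [x_ix, x_ix+1) x [y_iy, y_iy+1); the topmost/rightmost cells are closed
    so the counts always sum to n.
    """

    nx: int
    ny: int
    counts: np.ndarray  # shape (ny, nx)
    x_edges: np.ndarray
    y_edges: np.ndarray


def ground_truth_distance(fascicle: Fascicle, k: int, scope: str | None = None) -> float:
    """Observed mean kth-nearest-neighbor distance D_G for in-scope fibers."""
    pts = fascicle.coords(scope)
    if pts.shape[0] <= k:
        raise InsufficientPointsError(
            f"scope {scope or 'whole'!r} has {pts.shape[0]} fibers; "
            f"k={k} needs at least k+1 — use a smaller k"
        )
    return knn_mean_distance(pts, k)


def sdug(
    fascicle: Fascicle,
    null: NullDistribution,
    k: int | None = None,
    scope: str | None = None,
) -> SdugResult:
    """Standardize the observed D_G against a matching uniform null.

    The null must have been simulated with the same n (in-scope fiber
    count) and the same k; a mismatch raises :class:`ConsistencyError`.
    """
    k = null.k if k is None else k
    if k != null.k:
        raise ConsistencyError(f"requested k={k} but null was simulated at k={null.k}")
    n = len(fascicle.select(scope))
    if n != null.n:
        raise ConsistencyError(
            f"scope {scope or 'whole'!r} has n={n} fibers but null was simulated at n={null.n}"
        )
    d_g = ground_truth_distance(fascicle, k, scope)
    return SdugResult(
        d_g=d_g,
        sd_ug=(d_g - null.D_U) / null.sigma_U,
        k=k,
        n=n,
        null=null,
        scope=scope or "whole",
    )


def weighted_root_sdug(fascicle_results) -> float:
    """Fiber-count-weighted root-level index from per-fascicle results.

    Accepts ``(n_k, sd_ug_k)`` pairs or :class:`SdugResult` objects.
    """
    pairs = []
    for item in fascicle_results:
        if isinstance(item, SdugResult):
            pairs.append((item.n, item.sd_ug))
        else:
            n_k, sd_k = item
            pairs.append((int(n_k), float(sd_k)))
    if not pairs:
        raise ValueError("need at least one fascicle result")
    if any(n_k <= 0 for n_k, _ in pairs):
        raise ValueError("every fascicle weight n_k must be positive")
    total = sum(n_k for n_k, _ in pairs)
    return sum(n_k * sd_k for n_k, sd_k in pairs) / total


# -- L-function -------------------------------------------------------------


def _l_norm(points: np.ndarray, area: float, radii: np.ndarray) -> np.ndarray:
    """L(r) - r with the spec'd uncorrected K estimator.

    K(r) = (mean over points of the count of *other* points within r)
           divided by the intensity n / area.
    """
    n = points.shape[0]
    tree = cKDTree(points)
    pair_counts = tree.count_neighbors(tree, radii) - n  # remove self pairs
    k_hat = area * pair_counts / (n * n)
    return np.sqrt(k_hat / np.pi) - radii


def normalized_l_function(
    fascicle: Fascicle,
    radii: np.ndarray | None = None,
    n_simulations: int = 99,
    k_markers: tuple[int, ...] = (25, 50, 75),
    scope: str | None = None,
    random_state=None,
) -> LCurve:
    """Normalized L diagnostic with a same-region Monte-Carlo envelope.

    The envelope is the pointwise min/max of ``L(r) - r`` over
    ``n_simulations`` uniform placements of the same n in the same region;
    the observed curve rising above the upper envelope indicates clustering
    at that radius.  No edge correction is applied on either side, so the
    boundary bias is shared between curve and envelope.
    """
    pts = fascicle.coords(scope)
    n = pts.shape[0]
    if n < 2:
        raise InsufficientPointsError("the L-function needs at least 2 fibers")
    region = fascicle.region
    xmin, ymin, xmax, ymax = region.bounds
    if radii is None:
        rmax = 0.25 * min(xmax - xmin, ymax - ymin)
        radii = np.linspace(rmax / 64, rmax, 64)
    radii = np.asarray(radii, dtype=float)
    if not (np.all(np.diff(radii) > 0) and np.all(radii > 0)):
        raise ValueError("radii must be positive and strictly increasing")
    diam = float(np.hypot(xmax - xmin, ymax - ymin))
    if radii[-1] > diam:
        warnings.warn(
            f"largest radius {radii[-1]:g} exceeds the region diameter {diam:g}",
            stacklevel=2,
        )

    area = region.admissible_area
    observed = _l_norm(pts, area, radii)

    ss = (
        random_state
        if isinstance(random_state, np.random.SeedSequence)
        else np.random.SeedSequence(random_state)
    )
    sims = np.empty((n_simulations, radii.size))
    marker_sums = {k: 0.0 for k in k_markers if k < n}
    for s, child in enumerate(ss.spawn(n_simulations)):
        rng = np.random.default_rng(child)
        sim_pts = sample_uniform_points(region, n, rng)
        sims[s] = _l_norm(sim_pts, area, radii)
        for k in marker_sums:
            marker_sums[k] += knn_mean_distance(sim_pts, k)
    markers = {k: v / n_simulations for k, v in marker_sums.items()}
    return LCurve(
        radii=radii,
        l_norm=observed,
        envelope_lo=sims.min(axis=0),
        envelope_hi=sims.max(axis=0),
        k_markers=markers,
    )


def grid_intensity(fascicle: Fascicle, nx: int = 6, ny: int = 6, scope: str | None = None) -> GridIntensity:
    """Centroid counts over an nx-by-ny grid of the region bounding box."""
    if nx < 1 or ny < 1:
        raise ValueError(f"grid dimensions must be >= 1, got {nx}x{ny}")
    pts = fascicle.coords(scope)
    if pts.shape[0] < 1:
        raise InsufficientPointsError("grid intensity needs at least one fiber")
    xmin, ymin, xmax, ymax = fascicle.region.bounds
    counts, x_edges, y_edges = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=[nx, ny], range=[[xmin, xmax], [ymin, ymax]]
    )
    return GridIntensity(
        nx=nx, ny=ny, counts=counts.T.astype(int), x_edges=x_edges, y_edges=y_edges
    )


# -- group statistics -------------------------------------------------------


def group_compare(values_a, values_b) -> dict:
    """Two-sided Mann-Whitney U between two samples.

    Exact enumeration when both samples have n <= 8 and no ties across the
    pooled data; otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p": float(min(res.pvalue, 1.0)), "method": method}


def correlate(x, y) -> dict:
    """Pearson r and the coefficient of determination of the least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in x or y")
    r = float(sps.pearsonr(x, y).statistic)
    return {"pearson_r": r, "r_squared": r * r}


# -- estimator --------------------------------------------------------------


class ClusteringIndex(BaseEstimator):
    """SD_UG clustering index as a scikit-learn style estimator.

    Fits on an (n, 2) array of centroid coordinates (µm); the admissible
    region is passed to :meth:`fit` (it is data-dependent metadata, like
    sample weights).  The Monte-Carlo null is simulated at the same n and
    k unless a precomputed :class:`~fiberclust.null.NullDistribution` is
    supplied.

    Parameters
    ----------
    k : int
        Neighbor order of the mean-distance statistic.
    n_simulations : int
        Number of uniform placements for the null.
    random_state : int or None
        Master seed for the null simulations.

    Attributes
    ----------
    d_g_ : float
        Observed mean kNN distance (µm).
    null_ : NullDistribution
        The calibrating null (D_U, sigma_U).
    sd_ug_ : float
        The standardized index; negative = clustered.

    Examples
    --------
    >>> idx = ClusteringIndex(k=10, n_simulations=100, random_state=0)
    >>> idx.fit(points, region=region).sd_ug_  # doctest: +SKIP
    -6.2
    """

    def __init__(self, k: int = 50, n_simulations: int = 1000, random_state=None):
        self.k = k
        self.n_simulations = n_simulations
        self.random_state = random_state

    def fit(self, X, y=None, *, region: Region = None, null: NullDistribution = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(f"X must be an (n, 2) coordinate array, got shape {X.shape}")
        n = X.shape[0]
        if n <= self.k:
            raise InsufficientPointsError(f"n={n} fibers cannot support k={self.k}")
        if null is None:
            if region is None:
                raise ValueError("fit requires either region=... or a precomputed null=...")
            null = simulate_null(
                region, n=n, k=self.k, n_simulations=self.n_simulations,
                random_state=self.random_state,
            )
        if null.n != n or null.k != self.k:
            raise ConsistencyError(
                f"null (n={null.n}, k={null.k}) does not match data (n={n}, k={self.k})"
            )
        self.n_features_in_ = 2
        self.d_g_ = knn_mean_distance(X, self.k)
        self.null_ = null
        self.sd_ug_ = (self.d_g_ - null.D_U) / null.sigma_U
        return self

    def score(self, X=None, y=None) -> float:
        """Return the fitted SD_UG (more negative = more clustered)."""
        if not hasattr(self, "sd_ug_"):
            raise AttributeError("ClusteringIndex is not fitted yet")
        return self.sd_ug_
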