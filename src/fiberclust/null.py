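"""Monte-Carlo uniform null model for fiber placement.

The null hypothesis is complete spatial randomness (CSR) restricted to the
admissible region: n points placed uniformly over outer-minus-holes.  For
each of S independent placements the mean kth-nearest-neighbor distance

    d_s = (1/n) * sum_i d_ik

is recorded; their mean D_U and sample standard deviation sigma_U summarize
the null.  The same statistic computed on the observed centroids (D_G) is
later standardized against (D_U, sigma_U).

No edge correction is applied to the kNN distances: null and observed data
share the identical region, so boundary bias cancels in the comparison.

Reproducibility: randomness flows from a single ``numpy.random.SeedSequence``;
per-simulation generators are derived by ``spawn``, so simulation s is the
same whatever order (or parallelism) the simulations run in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import GeometryError, InsufficientPointsError
from .geometry import Region

__all__ = [
    "NullDistribution",
    "sample_uniform_points",
    "knn_mean_distance",
    "simulate_null",
]

#: abort rejection sampling when admissible/bbox area ratio is below this
_MIN_ACCEPT_RATIO = 1e-6


@dataclass(frozen=True)
class NullDistribution:
    """Summary of S uniform placements of n points at neighbor order k.

    Attributes
    ----------
    d_s : (S,) array
        Per-simulation mean kth-nearest-neighbor distances (µm).
    D_U, sigma_U : float
        Mean and sample standard deviation (ddof=1) of ``d_s`` (µm).
    """

    k: int
    n: int
    d_s: np.ndarray
    seed: int | None = None
    region_name: str = ""
    D_U: float = field(init=False)
    sigma_U: float = field(init=False)

    def __post_init__(self) -> None:
        d_s = np.asarray(self.d_s, dtype=float)
        if d_s.ndim != 1 or d_s.size < 2:
            raise ValueError("d_s must be a 1-D array with at least 2 simulations")
        if not np.all(d_s > 0):
            raise ValueError("all per-simulation mean distances must be positive")
        if not self.n >= self.k + 1:
            raise InsufficientPointsError(f"need n >= k+1, got n={self.n}, k={self.k}")
        object.__setattr__(self, "d_s", d_s)
        object.__setattr__(self, "D_U", float(d_s.mean()))
        object.__setattr__(self, "sigma_U", float(d_s.std(ddof=1)))

    @property
    def n_simulations(self) -> int:
        return int(self.d_s.size)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n": self.n,
            "S": self.n_simulations,
            "D_U": self.D_U,
            "sigma_U": self.sigma_U,
            "seed": self.seed,
            "region_name": self.region_name,
            "d_s": self.d_s.tolist(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def from_dict(cls, obj: dict) -> "NullDistribution":
        return cls(
            k=int(obj["k"]),
            n=int(obj["n"]),
            d_s=np.asarray(obj["d_s"], dtype=float),
            seed=obj.get("seed"),
            region_name=obj.get("region_name", ""),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NullDistribution":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def _as_rng(random_state) -> np.random.Generator:
    if isinstance(random_state, np.random.Generator):
        return random_state
    return np.random.default_rng(random_state)


def sample_uniform_points(region: Region, n: int, rng) -> np.ndarray:
    """Place n points uniformly over the admissible area of ``region``.

    Rejection sampling from the bounding box: exactly uniform over
    outer-minus-holes, and affine-equivariant under coordinate scaling or
    translation for a fixed random stream (draws are mapped as
    ``lo + u * (hi - lo)``).

    Raises
    ------
    GeometryError
        If the admissible/bbox area ratio is below 1e-6 (pathological
        region, rejection sampling would not terminate usefully).
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    rng = _as_rng(rng)
    xmin, ymin, xmax, ymax = region.bounds
    bbox_area = (xmax - xmin) * (ymax - ymin)
    accept = region.admissible_area / bbox_area
    if accept < _MIN_ACCEPT_RATIO:
        raise GeometryError(
            f"region {region.name!r}: admissible/bbox area ratio {accept:.2e} "
            f"below {_MIN_ACCEPT_RATIO:g}; rejection sampling is pathological"
        )
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = int((n - got) / accept * 1.1) + 16
        u = rng.random((m, 2))
        pts = np.column_stack(
            [xmin + u[:, 0] * (xmax - xmin), ymin + u[:, 1] * (ymax - ymin)]
        )
        ok = region.contains_xy(pts[:, 0], pts[:, 1])
        acc = pts[ok]
        take = min(n - got, acc.shape[0])
        out[got : got + take] = acc[:take]
        got += take
    return out


def knn_mean_distance(points: np.ndarray, k: int) -> float:
    """Mean Euclidean distance from each point to its kth-nearest other point.

    Ties are broken by distance value only: coincident neighbor distances
    give the same d_ik regardless of point ordering.

    Raises
    ------
    InsufficientPointsError
        If the number of points is <= k.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n <= k:
        raise InsufficientPointsError(
            f"kth-nearest-neighbor distance needs n >= k+1 points, got n={n}, k={k}"
        )
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=k + 1)  # column 0 is the point itself
    return float(dist[:, k].mean())


def simulate_null(
    region: Region,
    n: int,
    k: int = 50,
    n_simulations: int = 1000,
    random_state=None,
) -> NullDistribution:
    """Run the Monte-Carlo uniform null for (region, n, k).

    Parameters
    ----------
    n : int
        Points per placement; must be >= k+1.
    n_simulations : int
        Number S of independent placements (>= 2).
    random_state : int, SeedSequence, Generator, or None
        Master seed; per-simulation substreams are spawned from it.
    """
    if n_simulations < 2:
        raise ValueError(f"need at least 2 simulations, got {n_simulations}")
    if n < k + 1:
        raise InsufficientPointsError(f"need n >= k+1, got n={n}, k={k}")
    if isinstance(random_state, np.random.Generator):
        children = random_state.spawn(n_simulations)
        seed = None
    else:
        ss = (
            random_state
            if isinstance(random_state, np.random.SeedSequence)
            else np.random.SeedSequence(random_state)
        )
        children = [np.random.default_rng(c) for c in ss.spawn(n_simulations)]
        seed = random_state if isinstance(random_state, int) else None
    d_s = np.empty(n_simulations)
    for s, rng in enumerate(children):
        pts = sample_uniform_points(region, n, rng)
        d_s[s] = knn_mean_distance(pts, k)
    return NullDistribution(k=k, n=n, d_s=d_s, seed=seed, region_name=region.name)
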