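"""Spatial primitives: regions with vascular holes, fibers, fascicles, roots.

A :class:`Region` is the admissible 2D space for fiber centroids: the outer
contour of a root or fascicle endoneurium minus any vascular ("hole")
profiles.  Coordinates are real-valued micrometres in an arbitrary
section-local frame; no pixel calibration is performed here.

Boundary convention: a point exactly on the outer ring counts as inside, a
point exactly on a hole ring counts as outside, so the admissible set is
closed-minus-open.  Uniform rejection sampling almost surely never hits a
boundary, so the convention only matters for validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

from .exceptions import ContainmentError, GeometryError

__all__ = [
    "Region",
    "FiberClass",
    "FiberRecord",
    "Fascicle",
    "Root",
    "contains",
    "validate_fascicle",
]


class FiberClass(str, Enum):
    """Functional fiber category by diameter band."""

    PPN = "PPN"  # preganglionic parasympathetic, small
    GAMMA = "GAMMA"  # gamma motor, medium
    ALPHA = "ALPHA"  # alpha motor, large
    UNASSIGNED = "UNASSIGNED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _as_ring(ring: Iterable[Sequence[float]]) -> np.ndarray:
    arr = np.asarray(ring, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise GeometryError(f"a ring needs >= 3 (x, y) vertices, got shape {arr.shape}")
    # drop an explicit closing vertex; shapely closes rings itself
    if np.allclose(arr[0], arr[-1]) and arr.shape[0] > 3:
        arr = arr[:-1]
    return arr


@dataclass(frozen=True)
class Region:
    """Polygon-with-holes admissible space for fiber centroids (µm).

    Parameters
    ----------
    outer : (m, 2) array-like
        Vertex ring of the outer contour.  May be open or explicitly closed.
    holes : sequence of (m_i, 2) array-likes, optional
        Vascular hole rings; zero-area rings are dropped with a warning.
    name : str
        Identifier used in reports.
    """

    outer: np.ndarray
    holes: tuple[np.ndarray, ...] = ()
    name: str = ""
    _polygon: Polygon = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        outer = _as_ring(self.outer)
        shell = Polygon(outer)
        if not shell.is_valid:
            raise GeometryError(
                f"outer ring of region {self.name!r} is not a simple polygon "
                f"({shapely.is_valid_reason(shell)})"
            )
        if shell.area <= 0:
            raise GeometryError(f"outer ring of region {self.name!r} has zero area")

        kept: list[np.ndarray] = []
        for i, h in enumerate(self.holes):
            ring = _as_ring(h)
            poly = Polygon(ring)
            if poly.area == 0:  # degenerate rings are dropped before validity
                warnings.warn(
                    f"dropping zero-area hole {i} in region {self.name!r}",
                    stacklevel=2,
                )
                continue
            if not poly.is_valid:
                raise GeometryError(f"hole {i} of region {self.name!r} is not simple")
            if not shell.covers(poly):
                raise GeometryError(f"hole {i} of region {self.name!r} lies outside the outer ring")
            kept.append(ring)
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                inter = Polygon(kept[i]).intersection(Polygon(kept[j]))
                if inter.area > 0:
                    raise GeometryError(
                        f"holes {i} and {j} of region {self.name!r} overlap"
                    )
        polygon = Polygon(outer, kept)
        if polygon.area <= 0:
            raise GeometryError(f"region {self.name!r} has zero admissible area")
        object.__setattr__(self, "outer", outer)
        object.__setattr__(self, "holes", tuple(kept))
        object.__setattr__(self, "_polygon", polygon)
        object.__setattr__(self, "_shell", shell)
        object.__setattr__(self, "_hole_polys", tuple(Polygon(h) for h in kept))
        shapely.prepare(shell)
        for hp in self._hole_polys:
            shapely.prepare(hp)

    # -- derived geometry ---------------------------------------------------

    @property
    def polygon(self) -> Polygon:
        """The shapely polygon (exterior + interiors)."""
        return self._polygon

    @property
    def admissible_area(self) -> float:
        """Area of outer minus total hole area (µm²)."""
        return self._polygon.area

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer ring."""
        return self._polygon.bounds

    def contains_xy(self, x, y) -> np.ndarray:
        """Vectorized admissibility test under the boundary convention
        (on-outer = inside, on-hole = outside)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = shapely.intersects_xy(self._shell, x, y)  # closure of outer
        for hp in self._hole_polys:
            inside &= ~shapely.intersects_xy(hp, x, y)  # closure of hole
        return inside

    def scaled(self, factor: float) -> "Region":
        """Return the region with all coordinates multiplied by ``factor``."""
        return Region(
            outer=self.outer * factor,
            holes=tuple(h * factor for h in self.holes),
            name=self.name,
        )

    def translated(self, dx: float, dy: float) -> "Region":
        off = np.array([dx, dy])
        return Region(
            outer=self.outer + off,
            holes=tuple(h + off for h in self.holes),
            name=self.name,
        )


def contains(region: Region, x: float, y: float) -> bool:
    """True iff (x, y) is inside the outer ring and outside every hole."""
    return bool(region.contains_xy(x, y))


@dataclass
class FiberRecord:
    """One segmented myelinated fiber: centroid plus optional size metrics."""

    fiber_id: str
    x: float
    y: float
    area: float | None = None  # µm²
    perimeter: float | None = None  # µm
    diameter: float | None = None  # µm
    fiber_class: FiberClass = FiberClass.UNASSIGNED

    def __post_init__(self) -> None:
        if self.diameter is not None and not self.diameter > 0:
            raise ValueError(f"fiber {self.fiber_id!r}: diameter must be > 0")
        if isinstance(self.fiber_class, str) and not isinstance(self.fiber_class, FiberClass):
            self.fiber_class = FiberClass(self.fiber_class)


@dataclass
class Fascicle:
    """Fibers within one perineurial sheath, analyzed against one region."""

    region: Region
    fibers: list[FiberRecord]
    fascicle_id: str = "F1"

    @property
    def n_fibers(self) -> int:
        return len(self.fibers)

    def coords(self, scope: FiberClass | str | None = None) -> np.ndarray:
        """(n, 2) centroid array, optionally restricted to one fiber class."""
        fibers = self.select(scope)
        if not fibers:
            return np.empty((0, 2))
        return np.array([[f.x, f.y] for f in fibers], dtype=float)

    def select(self, scope: FiberClass | str | None = None) -> list[FiberRecord]:
        if scope is None or scope == "whole":
            return list(self.fibers)
        scope = FiberClass(scope)
        return [f for f in self.fibers if f.fiber_class == scope]


@dataclass
class Root:
    """A ventral root or peripheral nerve: one or more fascicles."""

    root_id: str
    animal_id: str
    fascicles: list[Fascicle]

    def __post_init__(self) -> None:
        if not self.fascicles:
            raise ValueError(f"root {self.root_id!r} needs at least one fascicle")
        ids = [f.fascicle_id for f in self.fascicles]
        if len(set(ids)) != len(ids):
            raise ValueError(f"root {self.root_id!r} has duplicate fascicle ids: {ids}")

    @property
    def n_fibers(self) -> int:
        return sum(f.n_fibers for f in self.fascicles)

    def all_fibers(self) -> list[FiberRecord]:
        return [fib for fas in self.fascicles for fib in fas.fibers]


def validate_fascicle(fascicle: Fascicle, policy: str = "warn") -> tuple[Fascicle, list[str]]:
    """Check the containment invariant for every fiber.

    Parameters
    ----------
    fascicle : Fascicle
    policy : {'error', 'drop', 'warn'}
        What to do with fibers whose centroid is outside the admissible
        space (outside the outer ring or inside a vascular hole).  The
        source data never states how such segmentation noise should be
        treated, so the policy is caller-selectable.

    Returns
    -------
    (fascicle, report)
        The (possibly filtered) fascicle and the list of violating fiber ids.
    """
    if policy not in ("error", "drop", "warn"):
        raise ValueError(f"unknown policy {policy!r}")
    coords = fascicle.coords()
    if coords.size == 0:
        return fascicle, []
    ok = fascicle.region.contains_xy(coords[:, 0], coords[:, 1])
    bad = [f.fiber_id for f, good in zip(fascicle.fibers, ok) if not good]
    if not bad:
        return fascicle, []
    if policy == "error":
        raise ContainmentError(
            f"fascicle {fascicle.fascicle_id!r}: {len(bad)} fiber(s) violate "
            f"region containment: {bad[:10]}"
        )
    if policy == "drop":
        keep = [f for f, good in zip(fascicle.fibers, ok) if good]
        return Fascicle(fascicle.region, keep, fascicle.fascicle_id), bad
    warnings.warn(
        f"fascicle {fascicle.fascicle_id!r}: fibers outside admissible space: {bad[:10]}",
        stacklevel=2,
    )
    return fascicle, bad
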