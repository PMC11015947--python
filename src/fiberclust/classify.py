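"""Fiber diameter estimation and functional classification.

Myelinated fibers in lumbosacral ventral roots fall into three diameter
bands that map onto functional populations: small (0-4 µm) preganglionic
parasympathetic (PPN), medium (>4-10 µm) gamma-motor, and large (>10 µm)
alpha-motor fibers.  Band edges are inclusive on the smaller class
(4.0 µm -> PPN, 10.0 µm -> GAMMA), matching the ">4" / ">10" interval
notation, and are user-overridable.

When a table supplies a diameter it is used verbatim.  When only area and
perimeter are available, :func:`effective_diameter` estimates the diameter
as the minor axis of the unique ellipse with that area and (Ramanujan-
approximated) perimeter — a documented stand-in for dispersion-angle
corrected diameters from upstream segmentation pipelines.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .exceptions import EmptyResultError, GeometryError
from .geometry import Fascicle, FiberClass, FiberRecord

__all__ = [
    "ClassBands",
    "effective_diameter",
    "classify_fiber",
    "assign_classes",
    "class_proportions",
]

#: relative tolerance for "perimeter is at least the circle minimum"
_CIRCLE_TOL = 1e-6


@dataclass(frozen=True)
class ClassBands:
    """Diameter band edges (µm) separating PPN / gamma / alpha fibers."""

    ppn_max: float = 4.0
    gamma_max: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.ppn_max < self.gamma_max:
            raise ValueError(f"need 0 < ppn_max < gamma_max, got {self.ppn_max}, {self.gamma_max}")


def effective_diameter(area: float, perimeter: float) -> float:
    """Diameter (µm) of a fiber from its cross-sectional area and perimeter.

    Solves for the semi-axes a >= b of the ellipse with ``area = pi*a*b``
    and Ramanujan's perimeter approximation
    ``P = pi*(3(a+b) - sqrt((3a+b)(a+3b)))`` and returns the minor axis
    ``2b``.  A circular fiber returns its circle diameter exactly; when the
    perimeter is within tolerance of the circle minimum (no ellipse fits),
    the equivalent-circle diameter ``2*sqrt(area/pi)`` is returned.

    Raises
    ------
    GeometryError
        If the perimeter is below the circular minimum for the area beyond
        tolerance (inconsistent segmentation), or inputs are non-positive.
    """
    if not (area > 0 and perimeter > 0):
        raise GeometryError(f"area and perimeter must be > 0, got {area}, {perimeter}")
    p_circle = 2.0 * math.sqrt(math.pi * area)
    if perimeter < p_circle * (1.0 - _CIRCLE_TOL):
        raise GeometryError(
            f"perimeter {perimeter:g} below the circular minimum {p_circle:g} "
            f"for area {area:g}: inconsistent segmentation"
        )
    d_circle = 2.0 * math.sqrt(area / math.pi)
    # Ramanujan with s = a+b, p = ab:  P/pi = 3s - sqrt(3s^2 + 4p)
    q = perimeter / math.pi
    p = area / math.pi
    s = (6.0 * q + math.sqrt(12.0 * q * q + 96.0 * p)) / 12.0
    disc = s * s - 4.0 * p
    if disc <= 0:
        return d_circle  # numerically circular
    b = (s - math.sqrt(disc)) / 2.0
    return min(2.0 * b, d_circle)


def classify_fiber(diameter: float, bands: ClassBands | None = None) -> FiberClass:
    """Assign a functional class from the fiber diameter (µm)."""
    bands = bands or ClassBands()
    if not diameter > 0:
        raise ValueError(f"diameter must be > 0, got {diameter}")
    if diameter <= bands.ppn_max:
        return FiberClass.PPN
    if diameter <= bands.gamma_max:
        return FiberClass.GAMMA
    return FiberClass.ALPHA


def assign_classes(
    fibers: Iterable[FiberRecord],
    bands: ClassBands | None = None,
    use_effective_diameter: bool = True,
) -> list[FiberRecord]:
    """Fill in diameter (where derivable) and fiber_class for each record.

    A supplied diameter wins; otherwise, with ``use_effective_diameter``,
    area + perimeter yield one via :func:`effective_diameter`.  Fibers with
    no usable size information stay UNASSIGNED.  Records are mutated and
    returned for chaining.
    """
    bands = bands or ClassBands()
    out = []
    for f in fibers:
        if f.diameter is None and use_effective_diameter and f.area and f.perimeter:
            f.diameter = effective_diameter(f.area, f.perimeter)
        if f.diameter is not None:
            f.fiber_class = classify_fiber(f.diameter, bands)
        out.append(f)
    return out


def class_proportions(fascicles: Iterable[Fascicle]) -> dict[str, float]:
    """Proportions of PPN / GAMMA / ALPHA among classified fibers.

    The three fractions sum to 1; UNASSIGNED fibers are excluded from the
    denominator and reported separately under ``unassigned_count``.

    Raises
    ------
    EmptyResultError
        If no fiber carries a class.
    """
    counts = Counter(f.fiber_class for fas in fascicles for f in fas.fibers)
    n_classified = sum(counts[c] for c in (FiberClass.PPN, FiberClass.GAMMA, FiberClass.ALPHA))
    if n_classified == 0:
        raise EmptyResultError("no classified fibers: run assign_classes first")
    return {
        "PPN": counts[FiberClass.PPN] / n_classified,
        "GAMMA": counts[FiberClass.GAMMA] / n_classified,
        "ALPHA": counts[FiberClass.ALPHA] / n_classified,
        "unassigned_count": counts[FiberClass.UNASSIGNED],
    }
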