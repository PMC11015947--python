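"""Exception hierarchy for fiberclust.

All fiberclust errors derive from :class:`FiberclustError` so callers can
catch the whole family; most also derive from the closest builtin
(``ValueError`` / ``OSError``) so generic handling keeps working.
"""


class FiberclustError(Exception):
    """Base class for all fiberclust errors."""


class FormatError(FiberclustError, ValueError):
    """A delimited input file does not match the expected table dialect."""


class GeometryError(FiberclustError, ValueError):
    """Invalid or inconsistent region geometry (self-intersection, bad holes,
    impossible area/perimeter combinations, pathological acceptance ratio)."""


class ContainmentError(FiberclustError, ValueError):
    """One or more fibers violate the region-containment invariant."""


class InsufficientPointsError(FiberclustError, ValueError):
    """Too few points for the requested neighbor order or minimum cluster size."""


class InfeasibleThresholdError(FiberclustError, ValueError):
    """The SD threshold maps to a non-positive reachability cut for this null."""

    def __init__(self, message: str, min_feasible_sd: float | None = None):
        super().__init__(message)
        self.min_feasible_sd = min_feasible_sd


class ConsistencyError(FiberclustError, ValueError):
    """Null distribution and ground-truth data disagree on n or k."""


class EmptyResultError(FiberclustError, ValueError):
    """An aggregation was requested over zero usable records."""
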