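import numpy as np
import pytest

from fiberclust import Fascicle, FiberRecord, Region, synthetic_region

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


@pytest.fixture
def unit_square() -> Region:
    return Region(outer=UNIT_SQUARE, name="unit-square")


@pytest.fixture
def square_with_hole() -> Region:
    hole = np.array([[0.25, 0.25], [0.75, 0.25], [0.75, 0.75], [0.25, 0.75]])
    return Region(outer=UNIT_SQUARE, holes=(hole,), name="square-hole")


@pytest.fixture(scope="session")
def root_region() -> Region:
    """Root-sized irregular region with two vascular holes (~400 µm across)."""
    return synthetic_region(random_state=1)


def make_fascicle(region: Region, points: np.ndarray, **kwargs) -> Fascicle:
    fibers = [
        FiberRecord(fiber_id=f"f{i}", x=float(x), y=float(y), **kwargs)
        for i, (x, y) in enumerate(points)
    ]
    return Fascicle(region=region, fibers=fibers)
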