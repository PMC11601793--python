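import numpy as np
import pytest

from lobulemech.fem import PeriodicCellProblem, build_mesh
from lobulemech.geometry import UnitCellGeometry, classify_region, distance_fields


@pytest.fixture(scope="session")
def cell() -> UnitCellGeometry:
    return UnitCellGeometry()


@pytest.fixture(scope="session")
def fields(cell):
    """Distance fields on the standard 80x160 raster."""
    return distance_fields(cell)


@pytest.fixture(scope="session")
def region(cell):
    """Region labels on the standard 80x160 raster."""
    return classify_region(cell)


@pytest.fixture(scope="session")
def small_problem(cell):
    """A cheap 10x20 periodic cell problem for FE behavior tests."""
    return PeriodicCellProblem(build_mesh(10, 20, cell))


@pytest.fixture(scope="session")
def working_problem(cell):
    """The standard 40x80 working-mesh problem (shared; ~1 s per solve)."""
    return PeriodicCellProblem(build_mesh(40, 80, cell))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
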