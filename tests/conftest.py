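import numpy as np
import pytest

from rangeshift.bioclim import derive_bioclim
from rangeshift.climate import ClimateStack
from rangeshift.grid import GridSpec
from rangeshift.synth import make_climate


@pytest.fixture(scope="session")
def grid10() -> GridSpec:
    """A 10x10 grid at 0.5 degrees over 30-35 E, 36-41 N."""
    return GridSpec.from_bounds(30.0, 35.0, 36.0, 41.0, 0.5)


@pytest.fixture(scope="session")
def climate10(grid10) -> ClimateStack:
    return make_climate(grid10, seed=42)


@pytest.fixture(scope="session")
def bioclim10(climate10):
    return derive_bioclim(climate10)


def constant_climate(grid: GridSpec, temp: float = 10.0, precip: float = 100.0) -> ClimateStack:
    """Spatially and monthly constant climate (tmin = tmax = temp)."""
    shape = (12, *grid.shape)
    return ClimateStack(
        grid, np.full(shape, temp), np.full(shape, temp), np.full(shape, precip)
    )


@pytest.fixture(scope="session")
def const_climate10(grid10) -> ClimateStack:
    return constant_climate(grid10)
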