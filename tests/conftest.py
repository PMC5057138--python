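import numpy as np
import pytest

from coralpump import (
    Bathymetry,
    HabitatMask,
    OMParams,
    TidalForcing,
    build_grid,
    make_habitat_mask,
    make_tidal_flow,
)
from coralpump.synthflow import default_bathymetry


@pytest.fixture(scope="session")
def column_grid_600():
    """Single 600-m column, 32 levels — the coral-summit reference column."""
    b = Bathymetry(depth=np.full((1, 1), 600.0), dx=250.0, dy=250.0)
    return build_grid(b, 32)


@pytest.fixture(scope="session")
def no_coral_mask_1x1():
    return HabitatMask(
        coral=np.zeros((1, 1), bool), habitat_class=np.full((1, 1), "off_reef")
    )


@pytest.fixture(scope="session")
def small_slope_bathy():
    """12 x 8 plain tanh slope, 200-2000 m."""
    from coralpump.synthflow import make_bathymetry

    return make_bathymetry(nx=12, ny=8, shelf_depth=200.0, trough_depth=2000.0)


@pytest.fixture(scope="session")
def small_grid(small_slope_bathy):
    return build_grid(small_slope_bathy, 6)


@pytest.fixture(scope="session")
def study_domain():
    """The study-condition synthetic domain: 60x40 columns, 20 levels,
    one 380-m mound (summit 600 m), shelf-break ridge, 40%-coverage mask."""
    bathy = default_bathymetry()
    grid = build_grid(bathy, 20)
    mask = make_habitat_mask(bathy)
    return grid, mask


@pytest.fixture(scope="session")
def short_flows(study_domain):
    grid, _ = study_domain
    return make_tidal_flow(grid, TidalForcing(), 0.0, 2.0, 6.0)


@pytest.fixture()
def params():
    return OMParams()
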