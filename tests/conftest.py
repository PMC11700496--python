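import numpy as np
import pytest
from shapely.geometry import box

from solarconflict import (
    CategoricalRaster,
    GridSpec,
    PointSet,
    PolygonSet,
    Raster,
    SedCriteria,
)


@pytest.fixture
def spec6() -> GridSpec:
    """6x6 unit-cell grid with the north-west corner at (0, 6)."""
    return GridSpec(6, 6, 1.0, origin_x=0.0, origin_y=6.0)


@pytest.fixture
def ramp6(spec6) -> Raster:
    """Raster over spec6 with value r*6 + c (0..35)."""
    return Raster(spec6, np.arange(36, dtype=float).reshape(6, 6))


def build_toy_scene(spec):
    """Hand-checkable 6x6 siting scene.

    slope = col + 1 degrees (cols 0..4 pass the 5-degree rule);
    land cover wetland on rows 0-1, shrubland elsewhere;
    one substation at the center of cell (3, 2), buffer radius 1.5 cells
    (covers the 3x3 block rows 2-4 x cols 1-3);
    protected rectangle over cells rows 4-5 x cols 0-1;
    GHI = r*6 + c, so the top 30% of 36 cells are values >= 24.5.
    """
    slope = Raster(spec, np.tile(np.arange(1.0, 7.0), (6, 1)))
    codes = np.full((6, 6), 1.0)
    codes[:2, :] = 2.0
    landcover = CategoricalRaster(spec, codes, {1: "shrubland", 2: "wetland"})
    substations = PointSet([[2.5, 2.5]])  # center of cell (row 3, col 2)
    protected = PolygonSet([box(0.0, 0.0, 2.0, 2.0)])  # rows 4-5, cols 0-1
    ghi = Raster(spec, np.arange(36, dtype=float).reshape(6, 6))
    criteria = SedCriteria(
        slope_max_deg=5.0,
        buffer_radius_m=1.5,
        excluded_landcover=frozenset({"wetland"}),
        ghi_top_fraction=0.30,
    )
    return slope, landcover, substations, protected, ghi, criteria


@pytest.fixture
def toy_scene6(spec6):
    return build_toy_scene(spec6)
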