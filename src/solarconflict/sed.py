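"""Multi-criterion site suitability for utility-scale solar energy development.

Four binary criterion layers — gentle slope, suitable land cover, proximity
to a substation, and location outside protected areas — are summed, and
cells satisfying all four (sum equal to the layer count) form the SESA map
("sites suitable for solar energy"). Intersecting SESA with the top
fraction of the global-horizontal-irradiance (GHI) distribution yields the
final SED suitability map. Existing photovoltaic facilities can then be
scored against the map as an external plausibility check.

The criteria use strict AND logic: no weighting, no partial credit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .raster_core import (
    BinaryMask,
    CategoricalRaster,
    GridSpec,
    PointSet,
    PolygonSet,
    Raster,
    align_to,
    class_mask,
    distance_mask,
    equals_mask,
    mask_intersect,
    polygon_mask,
    quantile_mask,
    sum_overlay,
    threshold_mask,
)

logger = logging.getLogger(__name__)

#: 5 statute miles in metres.
FIVE_MILES_M = 8046.72

DEFAULT_EXCLUDED_LANDCOVER = frozenset(
    {"urban/built-up", "wetland", "open water", "forest", "snow/ice"}
)


@dataclass
class SedCriteria:
    """Thresholds defining the four siting criteria plus the GHI rule.

    Defaults: slope kept at <= 5 degrees, substation buffer of 5 miles
    (8046.72 m), the standard unsuitable land-cover exclusion list, GHI in
    the top 30%, and all four criterion layers required (sum == 4).
    """

    slope_max_deg: float = 5.0
    buffer_radius_m: float = FIVE_MILES_M
    excluded_landcover: frozenset[str] = DEFAULT_EXCLUDED_LANDCOVER
    ghi_top_fraction: float = 0.30
    required_sum: int = 4
    #: compute the GHI quantile over the full extent (default) or only
    #: within SESA cells
    ghi_quantile_within_sesa: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.ghi_top_fraction <= 1:
            raise ValueError("ghi_top_fraction must be in (0, 1]")
        self.excluded_landcover = frozenset(self.excluded_landcover)


@dataclass
class SedResult:
    """Criterion layers plus the SESA and (once GHI is applied) SED maps."""

    criterion_masks: dict[str, BinaryMask]
    sesa: BinaryMask
    sed: BinaryMask | None = None
    cells_suitable: int = 0
    area_km2: float = 0.0


def build_sesa(
    slope: Raster,
    landcover: CategoricalRaster,
    substations: PointSet,
    protected: PolygonSet,
    spec: GridSpec,
    criteria: SedCriteria | None = None,
) -> SedResult:
    """Overlay the four criterion layers and keep cells satisfying all of them.

    Each layer is reclassified to {0, 1}, the layers are summed, and SESA
    is the set of cells whose sum equals ``criteria.required_sum``. Unknown
    land-cover classes (absent from the exclusion list) count as suitable;
    this is logged loudly because it is an exclusion-based rule.
    """
    criteria = criteria or SedCriteria()
    slope = align_to(slope, spec)
    landcover = align_to(landcover, spec)

    kept_classes = set(landcover.legend.values()) - set(criteria.excluded_landcover)
    logger.info(
        "land-cover exclusion rule: excluding %s; classes treated as SUITABLE: %s",
        sorted(criteria.excluded_landcover & set(landcover.legend.values())),
        sorted(kept_classes),
    )

    masks = {
        "slope": threshold_mask(slope, criteria.slope_max_deg),
        "landcover": class_mask(
            landcover, criteria.excluded_landcover & set(landcover.legend.values())
        ),
        "substation_buffer": distance_mask(substations, spec, criteria.buffer_radius_m),
        "unprotected": polygon_mask(protected, spec, invert=True),
    }
    summed = sum_overlay(list(masks.values()))
    sesa = equals_mask(summed, criteria.required_sum)
    return SedResult(criterion_masks=masks, sesa=sesa)


def apply_ghi(result: SedResult, ghi: Raster, criteria: SedCriteria | None = None) -> SedResult:
    """Mask SESA by the top-fraction GHI cells, producing the SED map.

    The GHI quantile is computed over all non-missing GHI cells in the
    study extent by default (``ghi_quantile_within_sesa`` restricts it to
    SESA cells instead). Updates and returns ``result`` with the SED map
    and its cell count / area.
    """
    criteria = criteria or SedCriteria()
    ghi = align_to(ghi, result.sesa.spec)
    if criteria.ghi_quantile_within_sesa:
        restricted = ghi.values.copy()
        restricted[~result.sesa.one_set()] = np.nan
        ghi_for_quantile = Raster(ghi.spec, restricted)
    else:
        ghi_for_quantile = ghi
    ghi_mask = quantile_mask(ghi_for_quantile, criteria.ghi_top_fraction)
    sed = mask_intersect(result.sesa, ghi_mask)
    result.sed = sed
    result.cells_suitable = sed.count_ones()
    result.area_km2 = result.cells_suitable * sed.spec.cell_area_km2()
    return result


def facility_inclusion(sed: BinaryMask, facilities: PointSet) -> float:
    """Percentage of facility points whose containing cell is SED-suitable.

    Facilities outside the grid (or on cells with missing SED) count as not
    included; the former triggers a warning.
    """
    if len(facilities) == 0:
        raise ValueError("facility_inclusion requires at least one facility")
    row, col = sed.spec.point_to_cell(facilities.x, facilities.y)
    outside = row < 0
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} facilities fall outside the grid; counted as not included",
            stacklevel=2,
        )
    included = np.zeros(len(facilities), dtype=bool)
    inside = ~outside
    included[inside] = sed.values[row[inside], col[inside]] == 1
    return float(100.0 * included.sum() / len(facilities))
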