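"""Overlap between predicted species presence and SED-suitable land.

The headline statistic: the percentage of predicted-presence cells that
are also suitable for solar energy development,

    overlap_pct = 100 * (# cells presence==1 and SED==1) / (# cells presence==1),

with missing cells excluded — presence-missing cells never enter the
denominator (presence maps are clipped to species ranges upstream, so the
denominator counts in-range presence only), and cells where SED is missing
count in the denominator but not the numerator. Cells in both 1-sets are
the "critical areas" — conflict zones where development pressure meets
predicted habitat. The complementary SED-opportunity map removes priority
habitat from the SED map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .raster_core import BinaryMask, GridError, mask_intersect


@dataclass
class OverlapReport:
    species: str
    range_class: str
    n_presence_cells: int
    n_overlap_cells: int
    overlap_pct: float


def overlap_percentage(
    presence: BinaryMask,
    sed: BinaryMask,
    species: str = "species",
    range_class: str = "unspecified",
) -> OverlapReport:
    """Share of presence cells that fall inside the SED 1-set."""
    if presence.spec != sed.spec:
        raise GridError("presence and SED masks must share a GridSpec")
    pres = presence.one_set()
    n_presence = int(pres.sum())
    if n_presence == 0:
        raise ValueError("presence mask has no 1-cells")
    n_overlap = int((pres & sed.one_set()).sum())
    return OverlapReport(
        species, range_class, n_presence, n_overlap, 100.0 * n_overlap / n_presence
    )


def critical_areas(presence: BinaryMask, sed: BinaryMask) -> BinaryMask:
    """Conflict zones: 1 where presence and SED are both 1; NaN propagates."""
    return mask_intersect(presence, sed)


def sed_opportunity(sed: BinaryMask, priority_masks: Sequence[BinaryMask]) -> BinaryMask:
    """SED cells free of every priority-habitat mask.

    1 where SED is 1 and every priority mask is 0 or missing there; 0
    elsewhere on SED's non-missing support; missing where SED is missing.
    """
    for m in priority_masks:
        if m.spec != sed.spec:
            raise GridError("priority masks must share the SED GridSpec")
    blocked = np.zeros(sed.spec.shape, dtype=bool)
    for m in priority_masks:
        blocked |= m.one_set()
    out = np.where(sed.one_set() & ~blocked, 1.0, 0.0)
    out[~np.isfinite(sed.values)] = np.nan
    return BinaryMask(sed.spec, out)


def species_report(
    suite: Mapping[str, Mapping[str, BinaryMask]], sed: BinaryMask
) -> list[OverlapReport]:
    """One OverlapReport per (species, range class)."""
    if not suite:
        raise ValueError("species suite is empty")
    reports = []
    for species, by_class in suite.items():
        for range_class, presence in by_class.items():
            reports.append(overlap_percentage(presence, sed, species, range_class))
    return reports


def reports_to_frame(reports: Sequence[OverlapReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "range_class": r.range_class,
                "n_presence_cells": r.n_presence_cells,
                "n_overlap_cells": r.n_overlap_cells,
                "overlap_pct": r.overlap_pct,
            }
            for r in reports
        ]
    )
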