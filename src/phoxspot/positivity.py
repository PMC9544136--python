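"""Artifact-region exclusion and overall percent positivity.

Slides routinely carry artifactual positivity (hemosiderin deposition, tissue
folds, staining artifacts). Those areas are outlined as polygons and every
cell whose centroid falls inside any of them is removed before anything is
computed; the remaining cells define both the overall percentage and the
hot-spot search space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .errors import EmptyInputError
from .io import CellTable, RegionSet

__all__ = ["FilterReport", "filter_cells", "overall_positivity"]


@dataclass
class FilterReport:
    """Accounting of the exclusion step.

    ``per_region_counts`` attributes cells to every region containing them, so
    with overlapping regions the per-region sum can exceed ``n_excluded``;
    each cell is excluded (and counted in ``n_excluded``) exactly once.
    """

    n_input: int = 0
    n_excluded: int = 0
    n_retained: int = 0
    per_region_counts: list[tuple[str, int]] = field(default_factory=list)


def filter_cells(cells: CellTable, regions: RegionSet) -> tuple[CellTable, FilterReport]:
    """Remove cells whose centroid lies inside any exclusion polygon.

    A centroid exactly on a polygon boundary counts as inside and is excluded
    (conservative: the regions exist because their positivity is untrustworthy).
    Retained cells keep their original ids and relative order.
    """
    n = len(cells)
    if not len(regions):
        return cells, FilterReport(n_input=n, n_excluded=0, n_retained=n)

    points = shapely.points(cells.x, cells.y)
    inside_any = np.zeros(n, dtype=bool)
    per_region: list[tuple[str, int]] = []
    for name, poly in regions.regions:
        inside = shapely.covers(poly, points)
        per_region.append((name, int(inside.sum())))
        inside_any |= inside

    retained = cells.take(np.flatnonzero(~inside_any))
    report = FilterReport(
        n_input=n,
        n_excluded=int(inside_any.sum()),
        n_retained=len(retained),
        per_region_counts=per_region,
    )
    return retained, report


def overall_positivity(cells: CellTable) -> float:
    """Percent of cells labeled positive: 100 × n_positive / n_total.

    Full floating precision; the reporting layer rounds for display. The
    denominator is all cells, positive and negative. An empty table raises
    :class:`EmptyInputError` — "no cells" is not the same finding as "0%".
    """
    if len(cells) == 0:
        raise EmptyInputError("cannot compute positivity of an empty cell table")
    return 100.0 * cells.n_positive / len(cells)
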