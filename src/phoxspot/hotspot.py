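"""The 1 mm hot spot: locating the densest focus of positive cells.

The hot-spot center is the positive cell with the greatest number of other
positive cells within a 500 μm radius; the reported hot-spot statistic is the
percent positivity inside the 1 mm-diameter disc (radius 500 μm) about that
center. Slides whose overall positivity does not exceed an eligibility
threshold (0.05% by default) are not submitted for hot-spot analysis at all —
their hot spot is "not applicable", which is distinct from 0%.

Center *selection* runs on a 1-in-k random subsample of the cells (k = 4 by
default) purely for speed; the reported disc statistic is then computed on the
full post-exclusion table by default so no precision is lost (``stats_on``
switches this for sensitivity checks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyInputError, ParameterError
from .io import CellTable
from .positivity import overall_positivity

__all__ = [
    "HotspotParams",
    "HotspotResult",
    "NoHotspot",
    "downsample",
    "count_positive_neighbors",
    "select_center",
    "hotspot_statistics",
    "find_hotspot",
]

#: Hot spot is a 1 mm-diameter disc, i.e. radius 500 μm.
HOTSPOT_RADIUS_UM = 500.0


@dataclass
class HotspotParams:
    """Knobs of the hot-spot procedure.

    neighbor_radius
        μm; the fixed radius both for neighbor counting during center
        selection and for the reported disc (default 500, i.e. a 1 mm spot).
    downsample_factor
        1-in-k subsampling of the cell table before neighbor counting
        (default 4); factor 1 disables downsampling.
    downsample_seed
        Seed for the random subsample, recorded so runs reproduce exactly.
    downsample_mode
        ``"random"`` (default) or ``"systematic"`` (every k-th cell), the
        latter for sensitivity checks.
    eligibility_threshold
        Percent; slides must have overall positivity strictly above it.
    stats_on
        ``"full"`` (default) computes the disc statistic on the full table;
        ``"downsampled"`` computes it on the same subsample used for center
        selection.
    """

    neighbor_radius: float = HOTSPOT_RADIUS_UM
    downsample_factor: int = 4
    downsample_seed: int = 0
    downsample_mode: str = "random"
    eligibility_threshold: float = 0.05
    stats_on: str = "full"

    def __post_init__(self) -> None:
        if self.neighbor_radius <= 0:
            raise ParameterError("neighbor_radius must be > 0")
        if self.downsample_factor < 1:
            raise ParameterError("downsample_factor must be >= 1")
        if self.eligibility_threshold < 0:
            raise ParameterError("eligibility_threshold must be >= 0")
        if self.downsample_mode not in ("random", "systematic"):
            raise ParameterError("downsample_mode must be 'random' or 'systematic'")
        if self.stats_on not in ("full", "downsampled"):
            raise ParameterError("stats_on must be 'full' or 'downsampled'")


@dataclass
class HotspotResult:
    center_cell_id: int
    center_xy: tuple[float, float]
    radius: float
    n_positive_in_disc: int
    n_total_in_disc: int
    percent_positive: float
    neighbor_count_at_center: int
    downsample_factor_used: int


@dataclass
class NoHotspot:
    """The legitimate 'no hot spot computed' outcome, with its reason.

    Falsy, so ``if result:`` distinguishes it from a :class:`HotspotResult`.
    """

    reason: str

    def __bool__(self) -> bool:
        return False


def downsample(cells: CellTable, factor: int, seed: int = 0, mode: str = "random") -> CellTable:
    """Subsample 1-in-``factor`` cells, keeping original ids and relative order.

    Random mode draws a uniform sample without replacement of size
    ceil(n/factor) with the seeded generator; systematic mode takes every
    ``factor``-th cell. Factor 1 returns the input unchanged regardless of
    seed.
    """
    if factor < 1:
        raise ParameterError("downsample factor must be >= 1")
    if factor == 1:
        return cells
    n = len(cells)
    size = math.ceil(n / factor)
    if mode == "systematic":
        idx = np.arange(0, n, factor)[:size]
    elif mode == "random":
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=size, replace=False))
    else:
        raise ParameterError(f"unknown downsample mode {mode!r}")
    return cells.take(idx)


def count_positive_neighbors(cells: CellTable, radius: float) -> list[tuple[int, int]]:
    """For each positive cell, the number of OTHER positive cells within ``radius``.

    Distances are Euclidean in micron space; a neighbor at exactly the radius
    counts. Self is excluded. Returns (cell_id, count) pairs in table order;
    empty list when the table has no positive cell. Uses a k-d tree but is
    contractually identical to the quadratic all-pairs count.
    """
    if radius <= 0:
        raise ParameterError("neighbor radius must be > 0")
    pos_idx = np.flatnonzero(cells.positive)
    if pos_idx.size == 0:
        return []
    xy = cells.xy[pos_idx]
    tree = cKDTree(xy)
    # query_ball_point uses closed balls (distance <= r); subtract self.
    counts = tree.query_ball_point(xy, r=radius, return_length=True) - 1
    ids = cells.cell_id[pos_idx]
    return [(int(i), int(c)) for i, c in zip(ids, counts)]


def select_center(neighbor_counts: list[tuple[int, int]]) -> int:
    """Cell id with the maximal neighbor count; ties go to the smallest id."""
    if not neighbor_counts:
        raise EmptyInputError("no positive cells to select a center from")
    best_id, best_count = neighbor_counts[0]
    for cid, count in neighbor_counts[1:]:
        if count > best_count or (count == best_count and cid < best_id):
            best_id, best_count = cid, count
    return best_id


def hotspot_statistics(
    cells_full: CellTable, center_xy: tuple[float, float], radius: float
) -> tuple[int, int, float]:
    """Positive/total counts and percent positivity in the closed disc.

    ``cells_full`` should be the full post-exclusion table (not the subsample
    used for center selection). No edge correction at slide borders: a disc
    hanging over the edge simply contains fewer cells.
    """
    if radius <= 0:
        raise ParameterError("disc radius must be > 0")
    d2 = (cells_full.x - center_xy[0]) ** 2 + (cells_full.y - center_xy[1]) ** 2
    in_disc = d2 <= radius * radius
    n_total = int(in_disc.sum())
    n_pos = int((in_disc & cells_full.positive).sum())
    if n_total == 0:
        raise EmptyInputError("hot-spot disc contains no cells")
    return n_pos, n_total, 100.0 * n_pos / n_total


def find_hotspot(cells: CellTable, params: HotspotParams | None = None) -> HotspotResult | NoHotspot:
    """Run the full hot-spot procedure on a post-exclusion cell table.

    Eligibility gate (overall positivity strictly above the threshold), then
    downsample → count positive neighbors → pick the center (max count,
    smallest-id tie-break) → disc statistics. Deterministic given the table
    and params, including the downsample seed.
    """
    params = params or HotspotParams()
    if len(cells) == 0:
        raise EmptyInputError("cannot search for a hot spot in an empty cell table")

    overall = overall_positivity(cells)
    if overall <= params.eligibility_threshold:
        return NoHotspot(reason="below eligibility threshold")

    sub = downsample(
        cells, params.downsample_factor, seed=params.downsample_seed, mode=params.downsample_mode
    )
    counts = count_positive_neighbors(sub, params.neighbor_radius)
    if not counts:
        return NoHotspot(reason="no positive cells after downsampling")

    center_id = select_center(counts)
    neighbor_count = dict(counts)[center_id]
    row = int(np.flatnonzero(sub.cell_id == center_id)[0])
    center_xy = (float(sub.x[row]), float(sub.y[row]))

    stats_table = cells if params.stats_on == "full" else sub
    n_pos, n_total, percent = hotspot_statistics(stats_table, center_xy, params.neighbor_radius)

    return HotspotResult(
        center_cell_id=int(center_id),
        center_xy=center_xy,
        radius=params.neighbor_radius,
        n_positive_in_disc=n_pos,
        n_total_in_disc=n_total,
        percent_positive=percent,
        neighbor_count_at_center=int(neighbor_count),
        downsample_factor_used=params.downsample_factor,
    )
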