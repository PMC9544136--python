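"""Reading and writing every external format the pipeline touches.

All geometry lives in a single canonical coordinate space: microns, origin at
the slide's top-left, y increasing downward (the convention of detection
exports from whole-slide analysis software). Cell-detection tables are
delimited text with a header row, modeled on QuPath detection-measurement
exports (``Centroid X µm``, ``Centroid Y µm``, ``Classification``); exclusion
regions and hot-spot annotations are GeoJSON; the cohort table is CSV.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, shape

from .errors import CalibrationError, FormatError

__all__ = [
    "CellRecord",
    "CellTable",
    "ColumnMap",
    "LoadReport",
    "RegionSet",
    "ENTITY_GROUPS",
    "read_cell_table",
    "write_cell_table",
    "read_regions",
    "read_cohort_fixture",
    "write_cohort_table",
    "write_case_result",
    "read_case_result",
    "write_hotspot_annotation",
]

POSITIVE = "positive"
NEGATIVE = "negative"

#: Entity groups of the study cohort: one CNS-embryonal reference table row set
#: plus the peripheral neuroblastoma comparison groups.
ENTITY_GROUPS = (
    "ETMR",
    "other-CNS-embryonal",
    "glioma",
    "ATRT",
    "medulloblastoma",
    "pineoblastoma",
    "neuroblastoma-primary",
    "neuroblastoma-metastatic",
    "PLAGL2-NEC",
)

#: Entity groups that are peripheral neuroblastoma (the non-CNS comparison arm).
NEUROBLASTOMA_GROUPS = ("neuroblastoma-primary", "neuroblastoma-metastatic")


class CellRecord(NamedTuple):
    """One detected cell: centroid in microns plus a binary stain class."""

    cell_id: int
    x: float
    y: float
    label: str  # "positive" | "negative"


@dataclass
class LoadReport:
    """Bookkeeping from parsing a detection table."""

    n_rows: int = 0
    n_dropped: int = 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.n_rows} rows read, {self.n_dropped} dropped"


@dataclass
class CellTable:
    """Marked planar point pattern: cell centroids (μm) with positive/negative labels.

    Column-oriented: parallel numpy arrays rather than per-cell objects, since
    whole-slide exports run to hundreds of thousands of rows. ``cell_id``
    preserves original file order and survives filtering/downsampling, so a
    hot-spot center can always be traced back to its source row.
    """

    x: np.ndarray
    y: np.ndarray
    positive: np.ndarray
    cell_id: np.ndarray | None = None
    slide_id: str = ""
    calibration_note: str = "microns"
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.positive = np.asarray(self.positive, dtype=bool)
        if self.cell_id is None:
            self.cell_id = np.arange(self.x.size, dtype=np.int64)
        else:
            self.cell_id = np.asarray(self.cell_id, dtype=np.int64)
        n = self.x.size
        if not (self.y.size == self.positive.size == self.cell_id.size == n):
            raise ValueError("CellTable arrays must have equal length")
        if n and not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("cell coordinates must be finite")

    def __len__(self) -> int:
        return int(self.x.size)

    def __iter__(self) -> Iterator[CellRecord]:
        for i in range(len(self)):
            yield CellRecord(
                int(self.cell_id[i]),
                float(self.x[i]),
                float(self.y[i]),
                POSITIVE if self.positive[i] else NEGATIVE,
            )

    @property
    def n_positive(self) -> int:
        return int(self.positive.sum())

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array."""
        return np.column_stack([self.x, self.y])

    def take(self, indices: np.ndarray) -> "CellTable":
        """Row subset preserving cell ids and metadata."""
        return CellTable(
            x=self.x[indices],
            y=self.y[indices],
            positive=self.positive[indices],
            cell_id=self.cell_id[indices],
            slide_id=self.slide_id,
            calibration_note=self.calibration_note,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "x": self.x,
                "y": self.y,
                "label": np.where(self.positive, POSITIVE, NEGATIVE),
            }
        )


@dataclass
class ColumnMap:
    """Maps a detection export's columns onto the canonical schema.

    ``units`` is either ``"um"`` or ``"px"``; pixel exports additionally need
    ``microns_per_pixel``. ``positive_token`` is matched case-insensitively as
    a substring of the classification column, so QuPath-style intensity bins
    ("Positive: 2+") and prefixed classes ("PHOX2B: Positive") all collapse to
    positive.
    """

    x: str = "Centroid X µm"
    y: str = "Centroid Y µm"
    classification: str = "Classification"
    units: str = "um"
    microns_per_pixel: float | None = None
    positive_token: str = "positive"


@dataclass
class RegionSet:
    """Named exclusion polygons in micron coordinates."""

    regions: list[tuple[str, Polygon]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, poly in self.regions:
            if len(poly.exterior.coords) < 4:  # closed ring: first == last
                raise FormatError(f"region {name!r} has fewer than 3 vertices")
            if poly.area == 0:
                raise FormatError(f"region {name!r} has zero area")

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.regions]


def _scale_factor(column_map: ColumnMap) -> float:
    if column_map.units == "um":
        return 1.0
    if column_map.units == "px":
        if not column_map.microns_per_pixel:
            raise CalibrationError(
                "coordinates declared in pixels but no microns_per_pixel factor given"
            )
        return float(column_map.microns_per_pixel)
    raise CalibrationError(f"unknown coordinate units {column_map.units!r}")


def read_cell_table(
    path: str | Path,
    column_map: ColumnMap | None = None,
    slide_id: str | None = None,
) -> CellTable:
    """Parse a delimited detection export into a :class:`CellTable` in microns.

    TSV by default, comma accepted (sniffed from the header line). Rows whose
    coordinates fail to parse as finite numbers are dropped and counted in the
    table's ``load_report``. Raises :class:`FormatError` if a mapped column is
    missing and :class:`CalibrationError` for pixel units without a conversion
    factor.
    """
    path = Path(path)
    cmap = column_map or ColumnMap()
    scale = _scale_factor(cmap)

    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","

    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in (cmap.x, cmap.y, cmap.classification):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")

    xs = pd.to_numeric(df[cmap.x], errors="coerce")
    ys = pd.to_numeric(df[cmap.y], errors="coerce")
    ok = np.isfinite(xs.to_numpy(dtype=float)) & np.isfinite(ys.to_numpy(dtype=float))
    report = LoadReport(n_rows=len(df), n_dropped=int((~ok).sum()))

    cls = df[cmap.classification].fillna("").astype(str)
    positive = cls.str.lower().str.contains(cmap.positive_token.lower(), regex=False)

    return CellTable(
        x=xs.to_numpy(dtype=float)[ok] * scale,
        y=ys.to_numpy(dtype=float)[ok] * scale,
        positive=positive.to_numpy()[ok],
        slide_id=slide_id if slide_id is not None else path.stem,
        calibration_note=f"converted to microns from {cmap.units}",
        load_report=report,
    )


def write_cell_table(cells: CellTable, path: str | Path) -> None:
    """Write a QuPath-style TSV detection table (microns)."""
    df = pd.DataFrame(
        {
            "Centroid X µm": cells.x,
            "Centroid Y µm": cells.y,
            "Classification": np.where(cells.positive, "Positive", "Negative"),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path) -> RegionSet:
    """Read a GeoJSON FeatureCollection of Polygon features (micron coordinates).

    Each feature becomes one named region; the ``name`` property is preserved
    and missing names are auto-assigned. Any non-Polygon geometry (including
    MultiPolygon) is a :class:`FormatError` naming the offending feature.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    regions: list[tuple[str, Polygon]] = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        name = (feat.get("properties") or {}).get("name") or f"region_{i}"
        if geom.get("type") != "Polygon":
            raise FormatError(
                f"{path}: feature {name!r} has geometry {geom.get('type')!r}; "
                "only Polygon is supported"
            )
        regions.append((name, shape(geom)))
    return RegionSet(regions)


# ---------------------------------------------------------------------------
# Cohort table


def read_cohort_fixture(path: str | Path | None = None) -> pd.DataFrame:
    """Load a cohort table: one row per case, hot-spot N/A as missing values.

    With no path, loads the packaged 51-case reference cohort (case id, entity
    group, overall percent positivity, hot-spot percent positivity; cases below
    the 0.05% eligibility cutoff were never submitted for hot-spot analysis and
    carry a missing — not zero — hot-spot value).
    """
    if path is None:
        src = resources.files("phoxspot").joinpath("data/table1_cohort.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, dtype={"case_id": str})
    else:
        df = pd.read_csv(path, dtype={"case_id": str})
    required = {"case_id", "entity_group", "overall_percent", "hotspot_percent"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"cohort table missing columns: {sorted(missing)}")
    df["overall_percent"] = pd.to_numeric(df["overall_percent"])
    df["hotspot_percent"] = pd.to_numeric(df["hotspot_percent"])
    bad = df["overall_percent"].lt(0) | df["overall_percent"].gt(100)
    bad |= df["hotspot_percent"].lt(0) | df["hotspot_percent"].gt(100)
    if bad.any():
        raise FormatError("percent columns must lie in [0, 100]")
    return df


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort CSV; missing hot-spot values become empty fields, never 0."""
    df.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Case results


def _dataclass_to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _dataclass_to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _dataclass_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_dataclass_to_jsonable(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def write_case_result(result, path: str | Path) -> None:
    """Serialize a per-case result (overall %, hot spot, QC flags) to JSON."""
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_dataclass_to_jsonable(result), fh, indent=2)
            fh.write("\n")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"failed writing case result to {path}: {exc}") from exc


def read_case_result(path: str | Path) -> dict:
    """Load a per-case result JSON as a plain dict (lossless numeric round-trip)."""
    path = Path(path)
    try:
        with open(path, "r", encoding="utf-8") as fh:
            return json.load(fh)
    except OSError as exc:
        raise OSError(f"failed reading case result from {path}: {exc}") from exc


def circle_polygon(center: Sequence[float], radius: float, n_vertices: int = 64) -> list[list[float]]:
    """Closed ring approximating a circle, for GeoJSON annotation output."""
    cx, cy = float(center[0]), float(center[1])
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    ring = [[cx + radius * math.cos(t), cy + radius * math.sin(t)] for t in theta]
    ring.append(list(ring[0]))
    return ring


def write_hotspot_annotation(result, path: str | Path, slide_id: str = "") -> None:
    """Write the hot-spot disc as a GeoJSON Feature (64-vertex circle polygon).

    A portable replacement for drawing the region inside the slide viewer: any
    GeoJSON-aware annotation tool can overlay it on the slide.
    """
    ring = circle_polygon(result.center_xy, result.radius)
    feature = {
        "type": "Feature",
        "geometry": {"type": "Polygon", "coordinates": [ring]},
        "properties": {
            "slide_id": slide_id,
            "percent_positive": result.percent_positive,
            "n_positive": result.n_positive_in_disc,
            "n_total": result.n_total_in_disc,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(feature, fh, indent=2)
        fh.write("\n")
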