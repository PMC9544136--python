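"""Synthetic whole-slide detections: marked planar point patterns with known truth.

A simulated slide is a homogeneous Poisson scatter of cells over a rectangle,
each cell labeled positive with a location-dependent probability: a baseline
fraction everywhere, elevated inside planted circular clusters (the ground
truth "hot spots"), and overridden inside artifact polygons that mimic regions
of spurious staining. Because the planted cluster centers and fractions are
known, every downstream stage — exclusion, overall positivity, hot-spot center
selection, disc statistics — can be validated against ground truth without any
scanned slides.

Conventions match real detection exports: coordinates in microns, origin at
the slide's top-left, y increasing downward. Slide dimensions and density are
given in mm / cells-per-mm² because that is how slides are described at the
bench; everything is converted to microns internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Point, Polygon, box

from .errors import ConfigurationError
from .io import CellTable

__all__ = [
    "PlantedCluster",
    "ArtifactRegion",
    "SimulationConfig",
    "SimulationTruth",
    "generate_slide",
    "generate_cohort",
    "load_config",
]

UM_PER_MM = 1000.0


@dataclass
class PlantedCluster:
    """A circular focus of elevated positivity.

    ``center`` is (x, y) in microns, ``radius`` in microns, and
    ``positive_fraction`` the label probability inside the disc. Clusters
    elevate positivity, never depress it: the fraction must be at least the
    owning config's baseline.
    """

    center: tuple[float, float]
    radius: float
    positive_fraction: float


@dataclass
class ArtifactRegion:
    """A polygon of spurious positivity (e.g. a stain deposit or tissue fold)."""

    polygon: Polygon
    positive_fraction: float
    name: str = "artifact"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic slide.

    Defaults are the package's reference conditions: a 10×10 mm slide at
    2000 cells/mm² (≈200k cells) with a 0.5% baseline positive fraction —
    an essentially immunonegative background against which a planted cluster
    stands out. ``n_cells`` fixes the cell count exactly instead of drawing
    it Poisson, for exact-count tests.
    """

    slide_width: float = 10.0  # mm
    slide_height: float = 10.0  # mm
    cell_density: float = 2000.0  # cells per mm^2
    baseline_positive_fraction: float = 0.005
    clusters: list[PlantedCluster] = field(default_factory=list)
    artifact_regions: list[ArtifactRegion] = field(default_factory=list)
    seed: int = 0
    n_cells: int | None = None
    slide_id: str = ""

    def __post_init__(self) -> None:
        if self.slide_width <= 0:
            raise ConfigurationError("slide_width must be > 0")
        if self.slide_height <= 0:
            raise ConfigurationError("slide_height must be > 0")
        if self.cell_density <= 0:
            raise ConfigurationError("cell_density must be > 0")
        if not 0.0 <= self.baseline_positive_fraction <= 1.0:
            raise ConfigurationError("baseline_positive_fraction must lie in [0, 1]")
        w_um = self.slide_width * UM_PER_MM
        h_um = self.slide_height * UM_PER_MM
        for i, c in enumerate(self.clusters):
            if c.radius <= 0:
                raise ConfigurationError(f"clusters[{i}].radius must be > 0")
            if not 0.0 <= c.positive_fraction <= 1.0:
                raise ConfigurationError(f"clusters[{i}].positive_fraction must lie in [0, 1]")
            if c.positive_fraction < self.baseline_positive_fraction:
                raise ConfigurationError(
                    f"clusters[{i}].positive_fraction is below the baseline; "
                    "clusters elevate positivity, never depress it"
                )
            x, y = c.center
            if not (0.0 <= x <= w_um and 0.0 <= y <= h_um):
                raise ConfigurationError(f"clusters[{i}].center lies outside the slide rectangle")
        for i, a in enumerate(self.artifact_regions):
            if not 0.0 <= a.positive_fraction <= 1.0:
                raise ConfigurationError(
                    f"artifact_regions[{i}].positive_fraction must lie in [0, 1]"
                )
        if self.n_cells is not None and self.n_cells < 0:
            raise ConfigurationError("n_cells must be >= 0")


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside each generated slide."""

    planted_centers: list[tuple[float, float]]
    planted_fractions: list[float]
    expected_overall_fraction: float
    n_cells: int

    def __post_init__(self) -> None:
        if len(self.planted_centers) != len(self.planted_fractions):
            raise ConfigurationError("planted_centers and planted_fractions lengths differ")
        if not 0.0 <= self.expected_overall_fraction <= 1.0:
            raise ConfigurationError("expected_overall_fraction must lie in [0, 1]")


def _priority_clusters(config: SimulationConfig) -> list[PlantedCluster]:
    """Clusters in label-assignment priority: innermost (smallest radius) first,
    listed order breaking ties — so where clusters overlap, the innermost wins."""
    order = sorted(range(len(config.clusters)), key=lambda i: (config.clusters[i].radius, i))
    return [config.clusters[i] for i in order]


def expected_overall_fraction(config: SimulationConfig) -> float:
    """Analytic expected positive fraction: the area-weighted probability mixture.

    Partitions the slide rectangle into the disjoint regions induced by the
    assignment priority (innermost cluster ≻ artifact ≻ baseline, clusters
    clipped to the slide) and averages the label probabilities by exact area.
    """
    w_um = config.slide_width * UM_PER_MM
    h_um = config.slide_height * UM_PER_MM
    rect = box(0.0, 0.0, w_um, h_um)
    total_area = rect.area

    weighted = 0.0
    assigned = shapely.geometry.GeometryCollection()
    for c in _priority_clusters(config):
        disc = Point(c.center).buffer(c.radius, quad_segs=512).intersection(rect)
        fresh = disc.difference(assigned)
        weighted += fresh.area * c.positive_fraction
        assigned = assigned.union(fresh)
    for a in config.artifact_regions:
        fresh = a.polygon.intersection(rect).difference(assigned)
        weighted += fresh.area * a.positive_fraction
        assigned = assigned.union(fresh)
    weighted += (total_area - assigned.area) * config.baseline_positive_fraction
    return weighted / total_area


def _label_probabilities(config: SimulationConfig, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-cell positive-label probability under the priority rules."""
    prob = np.full(x.size, config.baseline_positive_fraction)
    claimed = np.zeros(x.size, dtype=bool)
    for c in _priority_clusters(config):
        d2 = (x - c.center[0]) ** 2 + (y - c.center[1]) ** 2
        inside = (d2 <= c.radius * c.radius) & ~claimed
        prob[inside] = c.positive_fraction
        claimed |= inside
    if config.artifact_regions:
        points = shapely.points(x, y)
        for a in config.artifact_regions:
            inside = shapely.covers(a.polygon, points) & ~claimed
            prob[inside] = a.positive_fraction
            claimed |= inside
    return prob


def generate_slide(config: SimulationConfig) -> tuple[CellTable, SimulationTruth]:
    """Draw one synthetic slide: a marked Poisson point pattern plus its truth.

    Cell count ~ Poisson(density × area) (or exactly ``n_cells`` if fixed),
    positions uniform on the rectangle, labels Bernoulli with the
    location-dependent probability. Pure function of the config, including its
    seed: identical configs give identical output.
    """
    rng = np.random.default_rng(config.seed)
    w_um = config.slide_width * UM_PER_MM
    h_um = config.slide_height * UM_PER_MM
    area_mm2 = config.slide_width * config.slide_height

    if config.n_cells is not None:
        n = int(config.n_cells)
    else:
        n = int(rng.poisson(config.cell_density * area_mm2))
    x = rng.uniform(0.0, w_um, size=n)
    y = rng.uniform(0.0, h_um, size=n)
    positive = rng.random(n) < _label_probabilities(config, x, y)

    cells = CellTable(
        x=x,
        y=y,
        positive=positive,
        slide_id=config.slide_id or f"sim-seed{config.seed}",
        calibration_note="synthetic, microns",
    )
    truth = SimulationTruth(
        planted_centers=[tuple(map(float, c.center)) for c in config.clusters],
        planted_fractions=[float(c.positive_fraction) for c in config.clusters],
        expected_overall_fraction=expected_overall_fraction(config),
        n_cells=n,
    )
    return cells, truth


def generate_cohort(
    configs: list[SimulationConfig], entities: list[str]
) -> list[tuple[CellTable, SimulationTruth, str]]:
    """One slide per config, tagged with its entity label; deterministic given seeds."""
    if len(configs) != len(entities):
        raise ConfigurationError(
            f"configs ({len(configs)}) and entities ({len(entities)}) must have equal length"
        )
    out = []
    for config, entity in zip(configs, entities):
        cells, truth = generate_slide(config)
        out.append((cells, truth, entity))
    return out


def load_config(path: str | Path) -> SimulationConfig:
    """Build a SimulationConfig from a JSON file.

    Schema (all keys optional, defaults as in :class:`SimulationConfig`)::

        {
          "slide_width": 10.0, "slide_height": 10.0,
          "cell_density": 2000.0, "baseline_positive_fraction": 0.005,
          "seed": 0, "n_cells": null, "slide_id": "",
          "clusters": [{"center": [x_um, y_um], "radius": r_um,
                        "positive_fraction": p}, ...],
          "artifact_regions": [{"ring": [[x, y], ...],
                                "positive_fraction": p, "name": "fold"}, ...]
        }
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    clusters = [
        PlantedCluster(
            center=tuple(c["center"]),
            radius=float(c["radius"]),
            positive_fraction=float(c["positive_fraction"]),
        )
        for c in doc.pop("clusters", [])
    ]
    artifacts = [
        ArtifactRegion(
            polygon=Polygon(a["ring"]),
            positive_fraction=float(a["positive_fraction"]),
            name=a.get("name", "artifact"),
        )
        for a in doc.pop("artifact_regions", [])
    ]
    return SimulationConfig(clusters=clusters, artifact_regions=artifacts, **doc)
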