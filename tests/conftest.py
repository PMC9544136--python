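import numpy as np
import pytest

from phoxspot import CellTable, PlantedCluster, SimulationConfig, generate_slide


def make_cells(x, y, positive, **kwargs) -> CellTable:
    return CellTable(
        x=np.asarray(x, dtype=float),
        y=np.asarray(y, dtype=float),
        positive=np.asarray(positive, dtype=bool),
        **kwargs,
    )


def brute_force_neighbor_counts(cells: CellTable, radius: float) -> list[tuple[int, int]]:
    """O(n^2) oracle: for each positive cell, other positive cells within radius."""
    out = []
    pos = [(int(cid), float(px), float(py))
           for cid, px, py, is_pos in zip(cells.cell_id, cells.x, cells.y, cells.positive)
           if is_pos]
    for cid, px, py in pos:
        count = 0
        for oid, ox, oy in pos:
            if oid == cid:
                continue
            if (px - ox) ** 2 + (py - oy) ** 2 <= radius * radius:
                count += 1
        out.append((cid, count))
    return out


@pytest.fixture
def cells_factory():
    return make_cells


@pytest.fixture
def neighbor_oracle():
    return brute_force_neighbor_counts


@pytest.fixture
def clustered_slide():
    """Reference-condition slide: 10x10 mm, 2000 cells/mm^2, 0.5% baseline,
    one planted 500 um cluster at 30% positivity in the slide center."""
    config = SimulationConfig(
        clusters=[PlantedCluster(center=(5000.0, 5000.0), radius=500.0, positive_fraction=0.30)],
        seed=11,
    )
    cells, truth = generate_slide(config)
    return cells, truth, config
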