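"""Shared fixtures: generated tissues and hand-built lattice fixtures."""

import numpy as np
import pytest

from epi3d.datatypes import (
    CellColumn,
    ColumnEntry,
    LayerCell,
    PolygonalLayer,
    SimulationConfig,
)
from epi3d.synthetic import generate_tissue


@pytest.fixture(scope="session")
def default_tissue():
    """Default synthetic pseudostratified tissue (periodic, with nuclei)."""
    return generate_tissue(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def bounded_tissue():
    """Large bounded (non-periodic) tissue for lattice-law statistics."""
    cfg = SimulationConfig(
        n_cells=600,
        n_layers=3,
        periodic=False,
        seed=2,
        domain_width=124.0,
        domain_height=124.0,
        base_area_cv=0.3,
        nuclear_volume_fraction=0.0,
        resolution=2.0,
    )
    return generate_tissue(cfg)


@pytest.fixture
def pentagon_with_hexagon_ring():
    """One interior pentagon surrounded by five border hexagons.

    The border cells' neighbour sets reference IDs outside the layer
    (unsegmented surroundings), which the layer must tolerate.
    """
    ring = list(range(2, 7))
    cells = [
        LayerCell(
            cell_id=1,
            area=10.0,
            neighbour_ids=frozenset(ring),
            interior=True,
        )
    ]
    for k, cid in enumerate(ring):
        left = ring[(k - 1) % 5]
        right = ring[(k + 1) % 5]
        phantoms = {100 + cid, 200 + cid, 300 + cid}
        cells.append(
            LayerCell(
                cell_id=cid,
                area=12.0,
                neighbour_ids=frozenset({1, left, right} | phantoms),
                interior=False,
            )
        )
    return PolygonalLayer(layer_index=0, z=0.0, cells=cells)


def make_column(neighbour_sets, areas=None, nuclear_areas=None, height=25.0,
                cell_id=1):
    """Build a CellColumn from a list of neighbour-ID sets."""
    n = len(neighbour_sets)
    zs = np.arange(n) / (n - 1) if n > 1 else np.array([0.0])
    if areas is None:
        areas = [50.0] * n
    if nuclear_areas is None:
        nuclear_areas = [None] * n
    entries = [
        ColumnEntry(
            layer_index=i,
            z=float(zs[i]),
            area=float(areas[i]),
            neighbour_ids=frozenset(neighbour_sets[i]),
            nuclear_area=nuclear_areas[i],
        )
        for i in range(n)
    ]
    return CellColumn(cell_id=cell_id, entries=entries, height=height)
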