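"""Layer construction from label images and polygonal lattice statistics."""

import numpy as np
import pytest

from epi3d.layers import build_layer, layer_stats, side_and_angle_tables
from epi3d.datatypes import LayerCell, PolygonalLayer
from epi3d.synthetic import (
    SimulationConfig,
    generate_tissue,
    hexagonal_label_image,
)


def brute_force_adjacency(labels, min_contact=2, periodic=False):
    """Oracle: scan every pixel's 4-neighbourhood and count label pairs."""
    H, W = labels.shape
    counts = {}
    for i in range(H):
        for j in range(W):
            a = labels[i, j]
            if a == 0:
                continue
            neigh = [(i + 1, j), (i, j + 1)]
            if periodic:
                if i == H - 1:
                    neigh.append((0, j))
                if j == W - 1:
                    neigh.append((i, 0))
            for i2, j2 in neigh:
                if i2 >= H or j2 >= W:
                    continue
                b = labels[i2, j2]
                if b == 0 or b == a:
                    continue
                key = (min(a, b), max(a, b))
                counts[key] = counts.get(key, 0) + 1
    adj = {}
    for (a, b), c in counts.items():
        if c >= min_contact:
            adj.setdefault(int(a), set()).add(int(b))
            adj.setdefault(int(b), set()).add(int(a))
    return adj


def block_grid():
    """3×3 grid of 9 square labels, 10 px each."""
    img = np.zeros((30, 30), dtype=np.int32)
    for r in range(3):
        for c in range(3):
            img[r * 10 : (r + 1) * 10, c * 10 : (c + 1) * 10] = r * 3 + c + 1
    return img


class TestBuildLayer:
    def test_block_grid_centre_cell(self):
        layer = build_layer(block_grid(), pixel_size=1.0, z=0.0)
        centre = layer.cell(5)
        assert centre.neighbour_ids == frozenset({2, 4, 6, 8})
        assert centre.interior
        assert [c.cell_id for c in layer.interior_cells] == [5]
        assert centre.area == 100.0

    def test_hexagonal_raster_all_six_neighbours(self):
        img = hexagonal_label_image(6, 6, cell_px=14)
        layer = build_layer(img, pixel_size=0.5, z=0.0, periodic=True)
        assert all(c.n == 6 for c in layer.cells)
        assert all(c.interior for c in layer.cells)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_adjacency_matches_brute_force_oracle(self, seed):
        cfg = SimulationConfig(
            n_cells=30, n_layers=3, seed=seed, domain_width=30.0,
            domain_height=30.0, resolution=2.0, nuclear_volume_fraction=0.3,
        )
        tissue = generate_tissue(cfg)
        labels = tissue.cell_labels[1]
        layer = build_layer(
            labels, pixel_size=tissue.pixel_size, z=0.5, periodic=True,
            check_connectivity=False,
        )
        oracle = brute_force_adjacency(labels, periodic=True)
        for cell in layer.cells:
            assert set(cell.neighbour_ids) == oracle.get(cell.cell_id, set())

    def test_scale_invariance(self):
        img = block_grid()
        a = layer_stats(build_layer(img, pixel_size=1.0, z=0.0))
        b = layer_stats(build_layer(img, pixel_size=3.0, z=0.0))
        assert b.n_bar == a.n_bar
        assert b.freq == a.freq
        assert b.area_cv == pytest.approx(a.area_cv)
        assert set(b.aw_table) == set(a.aw_table)
        for n in a.aw_table:
            assert b.aw_table[n][0] == pytest.approx(a.aw_table[n][0])
        lb = build_layer(img, pixel_size=3.0, z=0.0)
        la = build_layer(img, pixel_size=1.0, z=0.0)
        assert lb.cell(5).area == pytest.approx(9 * la.cell(5).area)

    def test_error_on_empty_image(self):
        with pytest.raises(ValueError, match="empty"):
            build_layer(np.zeros((10, 10), dtype=np.int32), 1.0, 0.0)

    def test_error_on_disconnected_label(self):
        img = np.ones((10, 10), dtype=np.int32)
        img[:, 5:] = 2
        img[0, 0] = 2  # label 2 split into two components
        with pytest.raises(ValueError, match="label 2"):
            build_layer(img, 1.0, 0.0)

    def test_error_on_float_labels(self):
        with pytest.raises(ValueError, match="integer"):
            build_layer(np.ones((5, 5), dtype=float), 1.0, 0.0)

    def test_wrapped_cell_connected_on_torus(self):
        img = np.ones((8, 8), dtype=np.int32) * 2
        img[:, :2] = 1
        img[:, -2:] = 1  # label 1 wraps across the seam
        layer = build_layer(img, 1.0, 0.0, periodic=True, min_contact=2)
        assert layer.cell(1).neighbour_ids == frozenset({2})


class TestLayerStats:
    def test_regular_hexagonal_lattice(self):
        img = hexagonal_label_image(6, 6, cell_px=14)
        layer = build_layer(img, pixel_size=0.5, z=0.0, periodic=True)
        st = layer_stats(layer)
        assert st.n_bar == 6.0
        assert st.hex_fraction == 1.0
        assert st.area_cv == 0.0
        assert st.aw_table[6][0] == 6.0
        assert st.lewis_table[6][0] == pytest.approx(1.0)

    def test_pentagon_ring_aw_value(self, pentagon_with_hexagon_ring):
        # one pentagon whose five neighbours are all hexagons: m(5) = 6
        st = layer_stats(pentagon_with_hexagon_ring)
        assert st.aw_table[5][0] == pytest.approx(6.0)
        assert st.n_bar == 5.0
        assert st.freq == {5: 1.0}
        assert 5 in st.low_count  # single-cell class is flagged

    def test_low_neighbour_cells_excluded_as_artefacts(self):
        cells = [
            LayerCell(1, 10.0, frozenset({2}), True),  # n=1: artefact
            LayerCell(2, 10.0, frozenset({1, 3, 4}), True),
            LayerCell(3, 10.0, frozenset({2, 4, 5}), True),
            LayerCell(4, 10.0, frozenset({2, 3, 5}), True),
            LayerCell(5, 10.0, frozenset({3, 4}), False),
        ]
        st = layer_stats(PolygonalLayer(0, 0.0, cells))
        assert st.n_cells == 3  # cells 2..4 only

    def test_no_interior_cells_fails(self):
        cells = [LayerCell(1, 5.0, frozenset({2, 3, 4}), False)]
        with pytest.raises(ValueError, match="interior"):
            layer_stats(PolygonalLayer(0, 0.0, cells))


def regular_polygon(n, radius=1.0, centre=(0.0, 0.0), phase=0.0):
    ang = phase + 2 * np.pi * np.arange(n) / n
    return np.column_stack(
        [centre[0] + radius * np.cos(ang), centre[1] + radius * np.sin(ang)]
    )


class TestSidesAndAngles:
    def _layer_with_polygons(self, polys):
        cells = []
        ids = list(range(1, len(polys) + 1))
        for cid, poly in zip(ids, polys):
            others = frozenset(i for i in ids if i != cid) or frozenset(
                {90, 91, 92}
            )
            cells.append(
                LayerCell(
                    cell_id=cid,
                    area=1.0,
                    neighbour_ids=others
                    if len(others) >= 3
                    else frozenset({90, 91, 92}),
                    interior=True,
                    polygon_vertices=poly,
                )
            )
        return PolygonalLayer(0, 0.0, cells)

    def test_regular_hexagon(self):
        layer = self._layer_with_polygons([regular_polygon(6)] * 4)
        side_table, angle_table = side_and_angle_tables(layer)
        assert angle_table[6] == pytest.approx(120.0)
        assert side_table[6] == pytest.approx(1.0)

    def test_square_lattice_angles(self):
        layer = self._layer_with_polygons([regular_polygon(4)] * 4)
        _, angle_table = side_and_angle_tables(layer)
        assert angle_table[4] == pytest.approx(90.0)

    @pytest.mark.parametrize("n", [3, 5, 7, 11])
    @pytest.mark.parametrize("phase", [0.0, 0.7])
    def test_internal_angles_sum_to_polygon_identity(self, n, phase):
        # irregular simple polygon: jittered radii around a circle
        rng = np.random.default_rng(n * 10 + int(phase * 10))
        ang = np.sort(rng.uniform(0, 2 * np.pi, n))
        radius = rng.uniform(0.5, 1.5, n)
        poly = np.column_stack(
            [radius * np.cos(ang + phase), radius * np.sin(ang + phase)]
        )
        from epi3d.layers import _internal_angles

        total = np.degrees(_internal_angles(poly).sum())
        assert total == pytest.approx((n - 2) * 180.0, rel=1e-9)

    def test_missing_vertices_listed(self):
        cells = [
            LayerCell(7, 1.0, frozenset({8, 9, 10}), True, None),
            LayerCell(8, 1.0, frozenset({7, 9, 10}), True, regular_polygon(4)),
            LayerCell(9, 1.0, frozenset({7, 8, 10}), True, regular_polygon(4)),
            LayerCell(10, 1.0, frozenset({7, 8, 9}), True, regular_polygon(4)),
        ]
        with pytest.raises(ValueError, match=r"\[7\]"):
            side_and_angle_tables(PolygonalLayer(0, 0.0, cells))


def test_bounded_layer_euler_range(bounded_tissue):
    # bounded lattices fall just below the toroidal value of six
    st = layer_stats(bounded_tissue.layers[1])
    assert st.n_cells >= 400
    assert 5.0 <= st.n_bar <= 6.5
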