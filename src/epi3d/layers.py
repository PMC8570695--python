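"""Per-layer polygonal lattice statistics from labelled cross-sections.

A layer is built from a 2D integer label image (0 = background / excluded),
the standard output of cell-boundary segmentation.  Two cells count as
neighbours when they share at least ``min_contact`` 4-connected boundary
pixel pairs; the default of 2 suppresses the spurious contacts that
single-pixel corners create at what should be three-way junctions.  Border
cells are kept in the adjacency graph — their neighbour numbers enter the
Aboav-Weaire sums of interior cells — but are excluded from statistics, as
are cells with fewer than three neighbours (segmentation artefacts).
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
from scipy import ndimage

from epi3d.datatypes import LayerCell, LayerStats, PolygonalLayer

__all__ = ["build_layer", "layer_stats", "side_and_angle_tables"]


def _connected_on_domain(mask: np.ndarray, periodic: bool) -> bool:
    """True if the True-region of ``mask`` is 4-connected (torus-aware)."""
    structure = ndimage.generate_binary_structure(2, 1)
    comp, ncomp = ndimage.label(mask, structure=structure)
    if ncomp <= 1:
        return True
    if not periodic:
        return False
    # union components that touch across the periodic seams
    parent = list(range(ncomp + 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for edge_a, edge_b in ((comp[0, :], comp[-1, :]), (comp[:, 0], comp[:, -1])):
        both = (edge_a > 0) & (edge_b > 0)
        for a, b in zip(edge_a[both], edge_b[both]):
            union(int(a), int(b))
    roots = {find(c) for c in range(1, ncomp + 1)}
    return len(roots) == 1


def _boundary_pairs(labels: np.ndarray, periodic: bool) -> Counter:
    """Count 4-connected pixel-pair contacts between distinct labels."""
    pairs = Counter()

    def _accumulate(a: np.ndarray, b: np.ndarray):
        mask = (a != b) & (a > 0) & (b > 0)
        lo = np.minimum(a[mask], b[mask])
        hi = np.maximum(a[mask], b[mask])
        for key in zip(lo.tolist(), hi.tolist()):
            pairs[key] += 1

    _accumulate(labels[:, :-1], labels[:, 1:])
    _accumulate(labels[:-1, :], labels[1:, :])
    if periodic:
        _accumulate(labels[:, -1], labels[:, 0])
        _accumulate(labels[-1, :], labels[0, :])
    return pairs


def build_layer(
    label_image: np.ndarray,
    pixel_size: float,
    z: float,
    layer_index: int = 0,
    min_contact: int = 2,
    periodic: bool = False,
    check_connectivity: bool = True,
) -> PolygonalLayer:
    """Build a :class:`PolygonalLayer` from a 2D integer label image.

    Parameters
    ----------
    label_image
        2D array of non-negative integers; 0 is background.
    pixel_size
        Side length of one pixel in µm; areas are pixel counts × pixel_size².
    z
        Relative apical-basal position of this section (0 = apical).
    min_contact
        Minimum number of shared 4-connected boundary pixel pairs for two
        labels to count as neighbours.
    periodic
        Treat the image as a torus (wrap adjacency across edges); all cells
        are then interior.

    Raises
    ------
    ValueError
        If the image is empty, contains negative labels, or any label is
        split into disconnected components.
    """
    labels = np.asarray(label_image)
    if labels.ndim != 2:
        raise ValueError("label image must be 2D")
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("label image must have an integer dtype")
    if labels.min() < 0:
        raise ValueError("labels must be non-negative")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    if ids.size == 0:
        raise ValueError("empty label image: no cells found")

    if check_connectivity:
        for lab in ids:
            if not _connected_on_domain(labels == lab, periodic):
                raise ValueError(f"label {int(lab)} has disconnected components")

    pairs = _boundary_pairs(labels, periodic)
    neighbours = {int(l): set() for l in ids}
    for (a, b), cnt in pairs.items():
        if cnt >= min_contact:
            neighbours[int(a)].add(int(b))
            neighbours[int(b)].add(int(a))

    if periodic:
        touches_edge = set()
    else:
        border = np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
        touches_edge = set(int(v) for v in np.unique(border) if v > 0)
        # contact with excluded (0) regions also disqualifies a cell
        zero_contact = _boundary_zero_contact(labels)
        touches_edge |= zero_contact

    area_by_id = dict(zip(ids.tolist(), counts.tolist()))
    cells = [
        LayerCell(
            cell_id=int(lab),
            area=float(area_by_id[int(lab)]) * pixel_size**2,
            neighbour_ids=frozenset(neighbours[int(lab)]),
            interior=int(lab) not in touches_edge,
        )
        for lab in ids
    ]
    return PolygonalLayer(layer_index=layer_index, z=float(z), cells=cells)


def _boundary_zero_contact(labels: np.ndarray) -> set:
    touching = set()
    for a, b in (
        (labels[:, :-1], labels[:, 1:]),
        (labels[:-1, :], labels[1:, :]),
    ):
        mask = (a > 0) & (b == 0)
        touching.update(int(v) for v in np.unique(a[mask]))
        mask = (b > 0) & (a == 0)
        touching.update(int(v) for v in np.unique(b[mask]))
    return touching


def _sem(values: np.ndarray) -> float:
    if values.size < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / math.sqrt(values.size))


def layer_stats(layer: PolygonalLayer) -> LayerStats:
    """Polygonal lattice statistics of one layer.

    Statistics run over interior cells with n ≥ 3 neighbours only; border
    cells still contribute their neighbour numbers to the Aboav-Weaire sums.
    The area CV uses the sample standard deviation (n − 1 denominator).
    """
    n_by_id = {c.cell_id: c.n for c in layer.cells}
    interior = [c for c in layer.interior_cells if c.n >= 3]
    if not interior:
        raise ValueError("layer has no interior cells with n >= 3")

    ns = np.array([c.n for c in interior])
    areas = np.array([c.area for c in interior])
    counts = Counter(ns.tolist())
    total = len(interior)
    freq = {n: c / total for n, c in sorted(counts.items())}
    n_bar = float(ns.mean())
    mean_area = float(areas.mean())
    area_cv = float(np.std(areas, ddof=1) / mean_area) if total > 1 else 0.0

    aw_table, lewis_table = {}, {}
    for n in sorted(counts):
        in_class = [c for c in interior if c.n == n]
        m_vals = np.array(
            [
                sum(n_by_id[nb] for nb in c.neighbour_ids) / c.n
                for c in in_class
            ]
        )
        aw_table[n] = (float(m_vals.mean()), _sem(m_vals))
        a_vals = np.array([c.area for c in in_class])
        lewis_table[n] = (float(a_vals.mean() / mean_area), _sem(a_vals) / mean_area)

    return LayerStats(
        layer_index=layer.layer_index,
        z=layer.z,
        n_cells=total,
        freq=freq,
        counts=dict(sorted(counts.items())),
        n_bar=n_bar,
        area_cv=area_cv,
        aw_table=aw_table,
        lewis_table=lewis_table,
        hex_fraction=freq.get(6, 0.0),
        low_count=frozenset(n for n, c in counts.items() if c < 3),
    )


def _internal_angles(vertices: np.ndarray) -> np.ndarray:
    """Interior angles (radians) of a simple polygon given an ordered ring."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
        raise ValueError("polygon requires an (k>=3, 2) vertex array")
    # enforce counter-clockwise orientation (shoelace)
    area2 = np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])
    if area2 < 0:
        v = v[::-1]
    e = np.roll(v, -1, axis=0) - v  # edge i: v_i -> v_{i+1}
    e_prev = np.roll(e, 1, axis=0)
    turn = np.arctan2(
        e_prev[:, 0] * e[:, 1] - e_prev[:, 1] * e[:, 0],
        (e_prev * e).sum(axis=1),
    )
    return np.pi - turn


def side_and_angle_tables(layer: PolygonalLayer):
    """Per-class mean side length (normalised) and mean internal angle.

    Requires ``polygon_vertices`` on every interior cell.  Returns
    ``(side_table, angle_table)`` where side_table maps n to the class mean
    edge length divided by the global mean edge length, and angle_table maps
    n to the class mean internal angle in degrees.
    """
    interior = [c for c in layer.interior_cells if c.n >= 3]
    missing = [c.cell_id for c in interior if c.polygon_vertices is None]
    if missing:
        raise ValueError(f"polygon_vertices missing for cells {missing}")

    all_sides = []
    per_class_sides: dict = {}
    per_class_angles: dict = {}
    for c in interior:
        v = np.asarray(c.polygon_vertices, dtype=float)
        sides = np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)
        angles = np.degrees(_internal_angles(v))
        k = v.shape[0]
        all_sides.append(sides)
        per_class_sides.setdefault(k, []).append(sides.mean())
        per_class_angles.setdefault(k, []).append(angles.mean())

    global_mean = float(np.concatenate(all_sides).mean())
    side_table = {
        k: float(np.mean(vals)) / global_mean
        for k, vals in sorted(per_class_sides.items())
    }
    angle_table = {
        k: float(np.mean(vals)) for k, vals in sorted(per_class_angles.items())
    }
    return side_table, angle_table
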