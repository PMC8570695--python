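"""Core data containers shared across the pipeline.

Conventions used throughout the package:

* the apical-basal axis is parameterised by the relative coordinate
  ``z`` in [0, 1], with 0 = apical and 1 = basal;
* layer index 0 is the apical-most section;
* lengths are in µm, areas in µm², volumes in µm³;
* neighbour relations are stored as symmetric sets of cell identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class LayerCell:
    """One cell's cross-section within a single tissue layer."""

    cell_id: int
    area: float
    neighbour_ids: frozenset
    interior: bool
    polygon_vertices: Optional[np.ndarray] = None  # (k, 2) ordered ring

    @property
    def n(self) -> int:
        """Neighbour number of this cross-section."""
        return len(self.neighbour_ids)


@dataclass
class PolygonalLayer:
    """One cross-section of the tissue: a polygonal lattice of cells.

    ``interior`` cells are the ones entering statistics; border cells are
    retained so that their neighbour numbers still contribute to the
    Aboav-Weaire sums of interior cells.
    """

    layer_index: int
    z: float
    cells: list  # list[LayerCell]

    def __post_init__(self):
        self._validate()

    def _validate(self):
        by_id = {c.cell_id: c for c in self.cells}
        if len(by_id) != len(self.cells):
            raise ValueError("duplicate cell_id in layer")
        for c in self.cells:
            if c.area <= 0:
                raise ValueError(f"cell {c.cell_id}: non-positive area")
            if c.cell_id in c.neighbour_ids:
                raise ValueError(f"cell {c.cell_id} is its own neighbour")
            for nb in c.neighbour_ids:
                other = by_id.get(nb)
                if other is not None and c.cell_id not in other.neighbour_ids:
                    raise ValueError(
                        f"asymmetric adjacency between {c.cell_id} and {nb}"
                    )

    @property
    def interior_cells(self) -> list:
        return [c for c in self.cells if c.interior]

    def cell(self, cell_id: int) -> LayerCell:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(cell_id)


@dataclass
class LayerStats:
    """Per-layer polygonal lattice statistics over interior cells.

    ``aw_table`` maps the neighbour number n to the observed mean neighbour
    number m(n) of the neighbours of n-sided cells; ``lewis_table`` maps n to
    the mean area of the class divided by the overall mean interior area.
    SEM values are sample std / sqrt(count) per class; classes with fewer
    than three cells are flagged in ``low_count`` rather than dropped.
    """

    layer_index: int
    z: float
    n_cells: int
    freq: dict  # n -> fraction
    counts: dict  # n -> int
    n_bar: float
    area_cv: float
    aw_table: dict  # n -> (m_n, sem)
    lewis_table: dict  # n -> (ratio, sem)
    hex_fraction: float
    side_table: Optional[dict] = None  # n -> mean side / global mean side
    angle_table: Optional[dict] = None  # n -> mean internal angle (deg)
    low_count: frozenset = frozenset()


@dataclass
class ColumnEntry:
    """One apical-basal section of a single cell column."""

    layer_index: int
    z: float
    area: float
    neighbour_ids: frozenset
    nuclear_area: Optional[float] = None


@dataclass
class CellColumn:
    """One cell's ordered stack of cross-sections, apical to basal."""

    cell_id: int
    entries: list  # list[ColumnEntry]
    height: float
    interior: bool = True

    def __post_init__(self):
        idx = [e.layer_index for e in self.entries]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError(f"column {self.cell_id}: entries not sorted by layer")
        zs = [e.z for e in self.entries]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError(f"column {self.cell_id}: z not strictly increasing")
        if any(e.area <= 0 for e in self.entries):
            raise ValueError(f"column {self.cell_id}: non-positive area")


@dataclass
class T1Event:
    """One lateral neighbour change between adjacent sections of a column.

    ``delta_n`` may be zero for a pure partner exchange (scutoid-type swap);
    the exchange point is unresolved between the two sections, so the event
    position is the midpoint of their z values.
    """

    cell_id: int
    interface_index: int
    rel_position: float
    delta_n: int
    gained_ids: frozenset
    lost_ids: frozenset
    delta_area: float
    delta_nuclear_area: Optional[float] = None

    def __post_init__(self):
        if not (self.gained_ids or self.lost_ids):
            raise ValueError("T1 event with empty gained and lost sets")
        if not 0.0 <= self.rel_position <= 1.0:
            raise ValueError("rel_position outside [0, 1]")


@dataclass
class TransitionStats:
    """Summary statistics of lateral T1 transitions over a set of columns."""

    counts_per_cell: dict  # cell_id -> int
    total: int
    n_cells: int
    mean: float
    variance: float
    dispersion_index: float
    mean_rel_position: float
    rel_position_ci95: tuple  # (lo, hi)
    inter_transition_distances: list  # µm
    chi2: Optional[float] = None
    dof: Optional[int] = None
    p_value: Optional[float] = None


@dataclass
class NucleusModel:
    """Ellipsoidal nucleus of one cell column.

    ``centre_z`` is the relative apical-basal position of the centre of mass
    (0 = apical); ``semi_axes`` are the three principal semi-axes in µm with
    the last one aligned to the apical-basal axis.
    """

    cell_id: int
    centre_z: float
    semi_axes: tuple  # (ax, ay, az) µm

    @property
    def volume(self) -> float:
        ax, ay, az = self.semi_axes
        return 4.0 / 3.0 * np.pi * ax * ay * az

    def cross_section_area(self, z: float, tissue_height: float) -> float:
        """Elliptic cross-section area (µm²) at relative depth ``z``; 0 if absent."""
        ax, ay, az = self.semi_axes
        dz = (z - self.centre_z) * tissue_height
        u = 1.0 - (dz / az) ** 2
        if u <= 0.0:
            return 0.0
        return np.pi * ax * ay * u


@dataclass
class NuclearMorphometry:
    """Measured nuclear shape descriptors.

    Ellipticity is defined as 1 − (shortest / longest principal semi-axis),
    so a sphere scores 0 and elongated nuclei score closer to 1.
    """

    cell_id: int
    volume: float
    ellipticity: float
    centre_z: float
    semi_axes: tuple
    per_layer_area: Optional[dict] = None  # layer_index -> µm²


@dataclass
class EllipseFit:
    """Geometric parameters of a least-squares ellipse fit."""

    centre: tuple  # (cx, cy)
    a: float  # major semi-axis
    b: float  # minor semi-axis
    orientation: float  # radians, major-axis angle
    rms_residual: float

    def __post_init__(self):
        if not self.a >= self.b > 0:
            raise ValueError("ellipse requires a >= b > 0")


@dataclass
class TubeGeometry:
    """Apical and basal ellipse semi-axes defining the local radius model.

    The analysed cells sit at the cusp of a nearly elliptic tube, where the
    local radius of curvature is that of the minor vertex, a²/b.
    """

    a_apical: float
    b_apical: float
    a_basal: float
    b_basal: float

    def __post_init__(self):
        vals = (self.a_apical, self.b_apical, self.a_basal, self.b_basal)
        if any(v <= 0 for v in vals):
            raise ValueError("semi-axes must be positive")
        if self.a_apical < self.b_apical or self.a_basal < self.b_basal:
            raise ValueError("major semi-axis a must satisfy a >= b")


@dataclass
class TheoryTable:
    """Predicted per-polygon-class quantities at a given area CV."""

    law: str  # 'lewis_linear' | 'quadratic'
    cv: float
    class_areas: dict  # n -> An/Abar
    class_fractions: dict  # n -> predicted fraction

    @property
    def hex_fraction(self) -> float:
        return self.class_fractions.get(6, 0.0)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic pseudostratified-epithelium generator.

    Defaults emulate an embryonic-lung-scale tube segment: ~140 columnar
    cells spanning a ~25 µm thick epithelium sampled in 30 sections, nuclei
    occupying ~55% of the cell volume and distributed along the whole
    apical-basal axis with an apical excess (interkinetic nuclear migration
    places mitoses apically).
    """

    n_cells: int = 140
    n_layers: int = 15  # ≈ 1.7 µm section spacing over a 25 µm epithelium
    tissue_height: float = 25.0  # µm
    domain_width: float = 60.0  # µm
    domain_height: float = 60.0  # µm
    periodic: bool = True
    nuclear_volume_fraction: float = 0.55
    nuclear_aspect: float = 1.5  # apical-basal elongation of nuclei
    iknm_positions: str = "apical_biased"  # or 'uniform'
    base_area_cv: float = 0.3
    seed: int = 0
    resolution: float = 2.5  # raster pixels per µm
    jitter: float = 0.25  # per-layer lateral seed jitter, µm
    lattice: str = "random"  # 'random' | 'hex'
    relax_steps: int = 2  # Lloyd relaxation steps before weight tuning

    def __post_init__(self):
        if self.n_layers < 3:
            raise ValueError("n_layers must be >= 3")
        if not 0.0 < self.nuclear_volume_fraction < 1.0:
            # a zero fraction is allowed as an explicit degenerate limit
            if self.nuclear_volume_fraction != 0.0:
                raise ValueError("nuclear_volume_fraction must lie in (0, 1)")
        if self.tissue_height <= 0 or self.domain_width <= 0 or self.domain_height <= 0:
            raise ValueError("lengths must be positive")
        if self.base_area_cv < 0:
            raise ValueError("base_area_cv must be non-negative")
        if self.nuclear_aspect <= 0:
            raise ValueError("nuclear_aspect must be positive")
        if self.periodic and self.n_cells < 7:
            raise ValueError("periodic domains require n_cells >= 7")
        if self.iknm_positions not in ("apical_biased", "uniform"):
            raise ValueError("iknm_positions must be 'apical_biased' or 'uniform'")
        if self.lattice not in ("random", "hex"):
            raise ValueError("lattice must be 'random' or 'hex'")

    @property
    def domain_area(self) -> float:
        return self.domain_width * self.domain_height


@dataclass
class SyntheticTissue:
    """A generated tissue: layers, cell columns, nuclei and label stacks."""

    layers: list  # list[PolygonalLayer], index 0 = apical
    columns: list  # list[CellColumn]
    nuclei: list  # list[NucleusModel]
    config: SimulationConfig
    cell_labels: np.ndarray = field(default=None, repr=False)  # (L, H, W) int
    nucleus_labels: np.ndarray = field(default=None, repr=False)
    pixel_size: float = 0.0  # µm per raster pixel
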