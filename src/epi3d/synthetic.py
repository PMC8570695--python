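"""Synthetic pseudostratified-epithelium generator.

The generator emulates the statistical structure of a segmented
pseudostratified epithelium: ~60–150 columnar cells spanning the full
apical-basal axis, sampled in 15–40 cross-sections, with cell
cross-sectional areas driven by a per-cell baseline plus the elliptic
cross-section of an interkinetically migrating nucleus.  Each section is
tessellated with a power diagram (weighted Voronoi) whose per-cell weights
are tuned by damped fixed-point iteration until realised areas match the
targets; neighbour relations then follow from shared tessellation edges.
Because nuclei bulge the cross-sectional area profile of their cell, area
redistribution between sections produces lateral T1 transitions without any
explicit transition mechanism.

The power diagram is evaluated on a raster: each pixel is assigned to the
cell minimising ``d² − w``.  This yields label images directly, conserves
the total area exactly, and keeps adjacency extraction identical to the
path used for real segmentation masks.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

from epi3d.datatypes import (
    CellColumn,
    ColumnEntry,
    LayerCell,
    NucleusModel,
    PolygonalLayer,
    SimulationConfig,
    SyntheticTissue,
)

__all__ = [
    "generate_tissue",
    "generate_poisson_columns",
    "hexagonal_label_image",
    "hexagonal_seed_points",
]


class PackingError(RuntimeError):
    """Nuclear load or weight tuning makes the layer targets unattainable."""


# ---------------------------------------------------------------------------
# seed-point layouts


def hexagonal_seed_points(n_rows: int, n_cols: int, width: float, height: float):
    """Triangular-lattice seed points on a periodic rectangle.

    ``n_rows`` must be even so the row offset wraps consistently.  The
    Voronoi diagram of these points is a hexagonal tiling.
    """
    if n_rows % 2:
        raise ValueError("n_rows must be even on a periodic domain")
    dy = height / n_rows
    dx = width / n_cols
    pts = np.empty((n_rows * n_cols, 2))
    k = 0
    for r in range(n_rows):
        x0 = 0.5 * dx * (r % 2)
        for c in range(n_cols):
            pts[k] = (x0 + c * dx, r * dy)
            k += 1
    return pts


def _hex_grid_shape(n_cells: int):
    """Factor n_cells into an (even rows) × cols triangular-lattice grid."""
    best = None
    for rows in range(2, n_cells + 1, 2):
        if n_cells % rows:
            continue
        cols = n_cells // rows
        # prefer near-square layouts (equilateral needs rows*dy ≈ cols*dx*√3/2)
        score = abs(rows - cols * np.sqrt(3) / 2)
        if best is None or score < best[0]:
            best = (score, rows, cols)
    if best is None:
        raise ValueError(f"n_cells={n_cells} has no even-row hex factorisation")
    return best[1], best[2]


def hexagonal_label_image(n_rows: int, n_cols: int, cell_px: int = 14) -> np.ndarray:
    """Exact periodic hexagonal label image with identical cells.

    Every cell's pixel set is a translate of one fundamental tile, so all
    areas are exactly equal (area CV = 0) and every cell has exactly six
    neighbours.  Labels run 1..n_rows·n_cols.

    The assignment maps each pixel centre to the nearest lattice point of
    the triangular lattice with basis a1 = (cell_px, 0),
    a2 = (cell_px/2, row_px); ties are broken in lattice-local coordinates,
    which makes the rule translation-invariant.
    """
    if n_rows % 2:
        raise ValueError("n_rows must be even for periodic wrapping")
    row_px = cell_px  # lattice row spacing in pixels
    H, W = n_rows * row_px, n_cols * cell_px
    a1 = np.array([cell_px, 0.0])
    a2 = np.array([cell_px / 2.0, row_px])
    A = np.stack([a1, a2], axis=1)  # columns are basis vectors
    Ainv = np.linalg.inv(A)

    yy, xx = np.meshgrid(np.arange(H) + 0.5, np.arange(W) + 0.5, indexing="ij")
    P = np.stack([xx.ravel(), yy.ravel()])  # (2, N) pixel centres
    F = Ainv @ P  # fractional lattice coordinates
    base = np.floor(F)
    best_d = np.full(P.shape[1], np.inf)
    best_lat = np.zeros((2, P.shape[1]), dtype=np.int64)
    # candidate lattice points around the cell; fixed order = deterministic,
    # translation-invariant tie-break
    for du in (0, 1, -1):
        for dv in (0, 1, -1):
            lat = base + np.array([[du], [dv]])
            delta = P - A @ lat
            d = (delta**2).sum(axis=0)
            take = d < best_d - 1e-9
            best_d[take] = d[take]
            best_lat[:, take] = lat[:, take].astype(np.int64)

    # lattice coords (u, v): position = u*a1 + v*a2 → row v, column index u.
    # Wrapping v by n_rows shifts x by n_rows/2 lattice steps, so the column
    # index must be corrected by the number of vertical wraps.
    u, v = best_lat
    row = np.mod(v, n_rows)
    wraps = (v - row) // n_rows
    col = np.mod(u + wraps * (n_rows // 2), n_cols)
    labels = (row * n_cols + col + 1).reshape(H, W)
    return labels.astype(np.int32)


# ---------------------------------------------------------------------------
# power-diagram tessellation


def _pairwise_d2(px_x, px_y, seeds, width, height, periodic):
    """Squared distances (n_pixels, n_cells) with optional minimum image."""
    dx = np.abs(px_x[:, None] - seeds[None, :, 0])
    dy = np.abs(px_y[:, None] - seeds[None, :, 1])
    if periodic:
        dx = np.minimum(dx, width - dx)
        dy = np.minimum(dy, height - dy)
    return dx**2 + dy**2


def _power_assign(d2, weights):
    return np.argmin(d2 - weights[None, :], axis=1)


class _RasterTessellator:
    """Pixel-wise power-diagram assignment with candidate pruning.

    Each pixel only competes among its k nearest seeds (toroidal metric on
    periodic domains); a guard detects pixels whose winner could lie
    outside the candidate list under the current weights and re-evaluates
    those exactly.
    """

    K = 24

    def __init__(self, px_x, px_y, width, height, periodic):
        self.px = np.column_stack([px_x, px_y])
        self.width, self.height = width, height
        self.periodic = periodic
        self.seeds = None

    def set_seeds(self, seeds):
        self.seeds = np.asarray(seeds, dtype=float)
        n = self.seeds.shape[0]
        k = min(self.K, n)
        if self.periodic:
            pts = np.mod(self.seeds, [self.width, self.height])
            tree = cKDTree(pts, boxsize=(self.width, self.height))
        else:
            tree = cKDTree(self.seeds)
        dist, idx = tree.query(self.px, k=k)
        self.d2c = dist**2  # (n_px, k), ascending
        self.idx = idx
        self.k = k
        self.n = n
        if n > 1:
            if self.periodic:
                stree = cKDTree(pts, boxsize=(self.width, self.height))
            else:
                stree = cKDTree(self.seeds)
            dnn = stree.query(
                pts if self.periodic else self.seeds, k=2
            )[0][:, 1]
            # a boundary between close seeds shifts by Δw/(2d): damp the
            # weight step of tightly spaced cells to keep the fixed point
            # stable
            self.step_scale = np.clip(dnn / np.median(dnn), 0.0, 1.0) ** 2
        else:
            self.step_scale = np.ones(n)

    def assign(self, weights):
        vals = self.d2c - weights[self.idx]
        am = np.argmin(vals, axis=1)
        rows = np.arange(vals.shape[0])
        chosen = self.idx[rows, am]
        if self.k < self.n:
            # a non-candidate cell j has d2 >= d2c[:, -1], hence power value
            # >= d2c[:, -1] - max(w); pixels not safely below that bound get
            # an exact evaluation over all cells
            bound = self.d2c[:, -1] - weights.max()
            bad = vals[rows, am] > bound
            if bad.any():
                d2 = _pairwise_d2(
                    self.px[bad, 0],
                    self.px[bad, 1],
                    self.seeds,
                    self.width,
                    self.height,
                    self.periodic,
                )
                chosen[bad] = np.argmin(d2 - weights[None, :], axis=1)
        return chosen


def power_adjacency(
    seeds: np.ndarray,
    weights: np.ndarray,
    width: float,
    height: float,
    periodic: bool,
) -> dict:
    """Exact power-diagram adjacency via the convex-hull lifting.

    Lifting seeds to (x, y, x² + y² − w), the lower convex hull's facets
    form the regular (weighted Delaunay) triangulation, whose edges are
    exactly the shared power-diagram faces.  Periodic domains are handled
    by tiling the seeds 3×3 and reading adjacency off the central copy;
    on a torus this yields a triangulation with mean neighbour number
    exactly six.
    """
    n = seeds.shape[0]
    if periodic:
        shifts = [
            (dx * width, dy * height)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
        ]
        pts = np.concatenate([seeds + np.array(s) for s in shifts])
        w = np.tile(weights, 9)
    else:
        pts = seeds
        w = weights
    lifted = np.column_stack([pts, (pts**2).sum(axis=1) - w])
    try:
        hull = ConvexHull(lifted)
    except Exception:
        # degenerate (co-circular) inputs: joggle deterministically
        hull = ConvexHull(lifted, qhull_options="QJ")
    adjacency = {i: set() for i in range(n)}
    lower = hull.equations[:, 2] < -1e-12  # facets facing downwards
    for simplex in hull.simplices[lower]:
        for a in simplex:
            for b in simplex:
                if a == b:
                    continue
                ca, cb = int(a % n), int(b % n)
                if ca != cb and (not periodic or a // n == 4 or b // n == 4):
                    adjacency[ca].add(cb)
                    adjacency[cb].add(ca)
    return adjacency


def tune_weights(
    assign_fn,
    targets: np.ndarray,
    pixel_area: float,
    weights: np.ndarray = None,
    tol: float = 0.01,
    max_iter: int = 200,
    eta: float = 0.4,
    const_phase: int = 60,
    anneal_scale: float = 40.0,
    step_scale: np.ndarray = None,
):
    """Damped fixed-point tuning of power-diagram weights to target areas.

    ``assign_fn(w)`` maps a weight vector to the pixel→cell assignment.
    Iterates ``w ← w + η_t (target − realised)``: a constant-step phase of
    ``const_phase`` iterations followed by annealed decay, which settles
    the raster-quantisation oscillation near the fixed point.  Converged
    when the mean absolute area error falls below ``tol`` × mean target
    area and no cell is empty.  Returns ``(assignment, weights,
    residual)``.
    """
    n = targets.size
    w = np.zeros(n) if weights is None else weights.copy()
    scale = np.ones(n) if step_scale is None else step_scale
    mean_t = targets.mean()
    assign = assign_fn(w)
    residual = np.inf
    for it in range(max_iter):
        areas = np.bincount(assign, minlength=n) * pixel_area
        residual = float(np.abs(areas - targets).mean() / mean_t)
        if residual <= tol and (areas > 0).all():
            return assign, w, residual
        eta_t = (
            eta
            if it < const_phase
            else eta / (1.0 + (it - const_phase) / anneal_scale)
        )
        w = w + eta_t * scale * (targets - areas)
        empty = (areas == 0) & (targets > 0)
        if empty.any():  # vanished cells get an undamped push back
            w[empty] += 0.5 * targets[empty]
        w -= w.mean()  # weights are defined up to a constant
        assign = assign_fn(w)
    areas = np.bincount(assign, minlength=n) * pixel_area
    residual = float(np.abs(areas - targets).mean() / mean_t)
    if residual > tol or (areas == 0).any():
        raise PackingError(
            f"weight tuning did not converge: mean |area error| "
            f"{residual:.3f} of mean target after {max_iter} iterations; "
            f"{int((areas == 0).sum())} empty cells"
        )
    return assign, w, residual


# ---------------------------------------------------------------------------
# nuclei


def _draw_nuclei(config: SimulationConfig, rng, baselines: np.ndarray):
    """Ellipsoidal nuclei with IKNM-style apical-basal placement."""
    n = config.n_cells
    H = config.tissue_height
    mean_cell_vol = config.domain_area / n * H
    cell_vols = baselines * mean_cell_vol
    # modest cell-to-cell spread of the volume ratio around the target
    ratios = config.nuclear_volume_fraction * rng.normal(1.0, 0.08, n).clip(0.7, 1.3)
    vols = ratios * cell_vols

    if config.iknm_positions == "apical_biased":
        apical = rng.random(n) < 0.2  # apical excess: mitoses occur apically
        z = np.where(
            apical,
            rng.uniform(0.0, 0.25, n),
            rng.uniform(0.15, 0.85, n),
        )
    else:
        z = rng.uniform(0.15, 0.85, n)

    nuclei = []
    for i in range(n):
        v = vols[i]
        r = (3.0 * v / (4.0 * np.pi * config.nuclear_aspect)) ** (1.0 / 3.0)
        az = config.nuclear_aspect * r
        if az > H / 2:  # keep the ellipsoid inside the tissue at equal volume
            az = H / 2
            r = np.sqrt(3.0 * v / (4.0 * np.pi * az))
        lo = az / H  # ellipsoid must fit within the tissue along z
        zc = float(np.clip(z[i], lo, 1.0 - lo))
        nuclei.append(
            NucleusModel(cell_id=i + 1, centre_z=zc, semi_axes=(r, r, az))
        )
    return nuclei


# ---------------------------------------------------------------------------
# main generator


def generate_tissue(config: SimulationConfig) -> SyntheticTissue:
    """Generate a synthetic pseudostratified tissue.

    Per cell, the per-layer target area is a baseline (drawn once with
    spread ``base_area_cv``) plus the nucleus's elliptic cross-section at
    that depth, rescaled so targets sum to the domain area in every layer.
    Each layer is tessellated by a power diagram of jittered seed points
    with weights tuned to the targets; adjacency comes from shared
    tessellation edges.  All randomness derives from ``config.seed``.

    Raises
    ------
    PackingError
        If the nuclear load exceeds the domain area in some layer, or the
        weight tuning fails to converge.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    W, H = config.domain_width, config.domain_height
    res = config.resolution
    W_px, H_px = int(round(W * res)), int(round(H * res))
    pixel_size = W / W_px
    if abs(H / H_px - pixel_size) > 1e-9:
        H_px = int(round(H / pixel_size))
    pixel_area = pixel_size**2

    # --- seed points ------------------------------------------------------
    if config.lattice == "hex":
        rows, cols = _hex_grid_shape(n)
        seeds = hexagonal_seed_points(rows, cols, W, H)
    else:
        seeds = rng.uniform([0, 0], [W, H], size=(n, 2))

    yy, xx = np.meshgrid(
        (np.arange(H_px) + 0.5) * pixel_size,
        (np.arange(W_px) + 0.5) * pixel_size,
        indexing="ij",
    )
    px_x, px_y = xx.ravel(), yy.ravel()
    tess = _RasterTessellator(px_x, px_y, W, H, config.periodic)
    zero_w = np.zeros(n)

    if config.lattice == "random":
        for _ in range(config.relax_steps):  # Lloyd: regularise the lattice
            tess.set_seeds(seeds)
            assign = tess.assign(zero_w)
            for i in range(n):
                mask = assign == i
                if not mask.any():
                    continue
                if config.periodic:  # circular mean per axis
                    for ax, pos, span in ((0, px_x, W), (1, px_y, H)):
                        ang = pos[mask] / span * 2 * np.pi
                        mean_ang = np.arctan2(
                            np.sin(ang).mean(), np.cos(ang).mean()
                        )
                        seeds[i, ax] = (mean_ang / (2 * np.pi)) % 1.0 * span
                else:
                    seeds[i] = (px_x[mask].mean(), px_y[mask].mean())

    # --- per-cell baselines and nuclei -----------------------------------
    if config.base_area_cv > 0:
        k = 1.0 / config.base_area_cv**2
        baselines = rng.gamma(k, 1.0 / k, n).clip(0.25, 4.0)
        # rank-match baselines to the relaxed Voronoi areas: large targets
        # on already-large cells, which keeps the weight tuning local
        tess.set_seeds(seeds)
        assign = tess.assign(zero_w)
        voronoi_areas = np.bincount(assign, minlength=n)
        perm = np.empty(n, dtype=int)
        perm[np.argsort(voronoi_areas)] = np.argsort(baselines)
        baselines = baselines[perm]
    else:
        baselines = np.ones(n)

    if config.nuclear_volume_fraction > 0:
        nuclei = _draw_nuclei(config, rng, baselines)
    else:
        nuclei = []

    zs = np.arange(config.n_layers) / (config.n_layers - 1)

    # per-layer target areas: baseline + nuclear elliptic cross-section
    nuc_area = np.zeros((config.n_layers, n))
    for nuc in nuclei:
        i = nuc.cell_id - 1
        for li, z in enumerate(zs):
            nuc_area[li, i] = nuc.cross_section_area(z, config.tissue_height)

    # Nuclei are deformable: where the summed rigid-ellipsoid cross-sections
    # would overfill a layer, they are compressed laterally to leave at
    # least 12% of the layer to cytoplasm.  A layer needing more than
    # 2-fold compression is declared an infeasible packing.
    domain_area = config.domain_area
    cap = 0.88
    targets = np.empty((config.n_layers, n))
    for li in range(config.n_layers):
        load = nuc_area[li].sum()
        if load > cap * domain_area:
            squeeze = cap * domain_area / load
            if squeeze < 0.5:
                raise PackingError(
                    f"layer {li}: nuclear cross-sections ({load:.0f} µm²) "
                    f"cannot be packed into the domain "
                    f"({domain_area:.0f} µm²); reduce nuclear_volume_fraction"
                )
            nuc_area[li] *= squeeze
            load = cap * domain_area
        cyto = baselines / baselines.sum() * (domain_area - load)
        t = cyto + nuc_area[li]
        # floor: even a nucleus-free section keeps a thin cytoplasmic stalk
        min_area = 2.5  # µm²
        floored = t < min_area
        if floored.any():
            deficit = (min_area - t[floored]).sum()
            t[floored] = min_area
            free = ~floored
            t[free] -= deficit * t[free] / t[free].sum()
        targets[li] = t

    # --- per-layer jitter (AR(1): columns stay contiguous) ----------------
    offsets = np.zeros((config.n_layers, n, 2))
    if config.jitter > 0:
        sigma = config.jitter
        rho = 0.7
        offsets[0] = rng.normal(0, sigma, (n, 2))
        for li in range(1, config.n_layers):
            offsets[li] = rho * offsets[li - 1] + np.sqrt(
                1 - rho**2
            ) * rng.normal(0, sigma, (n, 2))

    # --- tessellate each layer -------------------------------------------
    label_stack = np.empty((config.n_layers, H_px, W_px), dtype=np.int32)
    weights = None
    layers = []
    for li, z in enumerate(zs):
        pts = seeds + offsets[li]
        if config.periodic:
            pts = np.mod(pts, [W, H])
        else:
            pts = np.clip(pts, [0, 0], [W, H])
        tess.set_seeds(pts)
        # escalating attempts: warm start first, then fresh weights with a
        # longer constant phase and slower annealing for hard layers
        attempts = (
            dict(weights=weights),
            dict(weights=None, max_iter=300, const_phase=120,
                 anneal_scale=60.0),
            dict(weights=None, max_iter=500, const_phase=150,
                 anneal_scale=100.0),
        )
        last_exc = None
        for kwargs in attempts:
            try:
                assign, weights, _ = tune_weights(
                    tess.assign, targets[li], pixel_area,
                    step_scale=tess.step_scale, **kwargs
                )
                last_exc = None
                break
            except PackingError as exc:
                last_exc = exc
        if last_exc is not None:
            raise PackingError(f"layer {li}: {last_exc}") from last_exc
        label_stack[li] = (assign + 1).reshape(H_px, W_px).astype(np.int32)
        areas = np.bincount(assign, minlength=n) * pixel_area
        adjacency = power_adjacency(pts, weights, W, H, config.periodic)
        if config.periodic:
            border = set()
        else:
            img = label_stack[li]
            border = {
                int(v) - 1
                for v in np.unique(
                    np.concatenate([img[0], img[-1], img[:, 0], img[:, -1]])
                )
            }
        layers.append(
            PolygonalLayer(
                layer_index=li,
                z=float(z),
                cells=[
                    LayerCell(
                        cell_id=i + 1,
                        area=float(areas[i]),
                        neighbour_ids=frozenset(j + 1 for j in adjacency[i]),
                        interior=i not in border,
                    )
                    for i in range(n)
                ],
            )
        )

    # --- nucleus label stack ---------------------------------------------
    nucleus_stack = np.zeros_like(label_stack)
    if nuclei:
        centres = np.array(
            [seeds[nuc.cell_id - 1] for nuc in nuclei]
        )  # nuclei follow the column axis
        r_lat = np.array([nuc.semi_axes[0] for nuc in nuclei])
        az = np.array([nuc.semi_axes[2] for nuc in nuclei])
        zc = np.array([nuc.centre_z for nuc in nuclei])
        for li, z in enumerate(zs):
            dz = (z - zc) * config.tissue_height
            u = 1.0 - (dz / az) ** 2
            r_z = np.where(u > 0, r_lat * np.sqrt(np.maximum(u, 0)), 0.0)
            assign = label_stack[li].ravel() - 1
            cx = centres[assign, 0]
            cy = centres[assign, 1]
            dx = np.abs(px_x - cx)
            dy = np.abs(px_y - cy)
            if config.periodic:
                dx = np.minimum(dx, W - dx)
                dy = np.minimum(dy, H - dy)
            inside = dx**2 + dy**2 <= r_z[assign] ** 2
            nucleus_stack[li] = np.where(
                inside.reshape(H_px, W_px), label_stack[li], 0
            )

    # --- columns ----------------------------------------------------------
    nuc_by_id = {nuc.cell_id: nuc for nuc in nuclei}
    columns = []
    for i in range(n):
        cid = i + 1
        entries = []
        for li, z in enumerate(zs):
            cell = layers[li].cell(cid)
            na = None
            if cid in nuc_by_id:
                a = nuc_by_id[cid].cross_section_area(
                    float(z), config.tissue_height
                )
                na = a if a > 0 else None
            entries.append(
                ColumnEntry(
                    layer_index=li,
                    z=float(z),
                    area=cell.area,
                    neighbour_ids=cell.neighbour_ids,
                    nuclear_area=na,
                )
            )
        interior = all(layers[li].cell(cid).interior for li in range(config.n_layers))
        columns.append(
            CellColumn(
                cell_id=cid,
                entries=entries,
                height=config.tissue_height,
                interior=interior,
            )
        )

    return SyntheticTissue(
        layers=layers,
        columns=columns,
        nuclei=nuclei,
        config=config,
        cell_labels=label_stack,
        nucleus_labels=nucleus_stack,
        pixel_size=pixel_size,
    )


# ---------------------------------------------------------------------------
# abstract Poisson columns


def generate_poisson_columns(
    n_cells: int,
    rate: float,
    n_layers: int = 30,
    seed: int = 0,
    height: float = 25.0,
) -> list:
    """Abstract cell columns with Poisson-distributed neighbour-set changes.

    Each column carries a constant baseline neighbour set; a
    Poisson(``rate``)-distributed number of interfaces (placed uniformly at
    random, at most one change per interface) swap, add or drop one
    neighbour ID.  Used to exercise the T1 statistics in isolation.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if n_layers < 2:
        raise ValueError("n_layers must be >= 2")
    rng = np.random.default_rng(seed)
    zs = np.arange(n_layers) / (n_layers - 1)
    columns = []
    fresh = n_cells * 100  # opaque IDs for swapped-in neighbours
    for c in range(n_cells):
        base = set(range(c * 10 + 1, c * 10 + 7))  # six arbitrary neighbours
        k = min(int(rng.poisson(rate)), n_layers - 1)
        cuts = set(
            rng.choice(n_layers - 1, size=k, replace=False).tolist()
        )
        current = set(base)
        entries = []
        areas = 50.0 + rng.normal(0, 2.0, n_layers)
        for li in range(n_layers):
            if li > 0 and (li - 1) in cuts:
                op = rng.random()
                if op < 0.6 or len(current) <= 3:  # swap one partner
                    lost = rng.choice(sorted(current))
                    current = (current - {lost}) | {fresh}
                elif op < 0.8:  # gain
                    current = current | {fresh}
                else:  # lose
                    lost = rng.choice(sorted(current))
                    current = current - {lost}
                fresh += 1
            entries.append(
                ColumnEntry(
                    layer_index=li,
                    z=float(zs[li]),
                    area=float(max(areas[li], 1.0)),
                    neighbour_ids=frozenset(current),
                )
            )
        columns.append(CellColumn(cell_id=c + 1, entries=entries, height=height))
    return columns
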