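"""Ellipse-based local tissue-curvature model for tubular epithelia.

Collapsed epithelial tubes have nearly elliptic apical and basal surface
boundaries.  For cells sitting at the cusp (minor vertex) of such a tube,
the local radius of curvature of an ellipse with semi-axes a ≥ b is a²/b
(the minor-vertex curvature is b/a²).  Interpolating the semi-axes linearly
between the apical (x = 0) and basal (x = 1) surfaces gives the local
radius model

    R(x) = (a_ap + x·(a_ba − a_ap))² / (b_ap + x·(b_ba − b_ap)),

which assigns a curvature radius to every relative apical-basal position,
and hence a curvature fold change R2/R1 to every pair of consecutive
lateral T1 transitions of a cell.
"""

from __future__ import annotations

import math

import numpy as np

from epi3d.datatypes import EllipseFit, TubeGeometry
from epi3d.t1 import detect_t1

__all__ = [
    "fit_ellipse",
    "local_radius",
    "event_fold_changes",
    "fold_change_summary",
    "predicted_fold",
    "register_fold_model",
]


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Direct least-squares ellipse fit (numerically stable formulation).

    Fits the conic Ax² + Bxy + Cy² + Dx + Ey + F = 0 subject to the
    ellipse constraint 4AC − B² = 1 by the block-decomposed eigenproblem,
    then extracts geometric parameters.  The reported residual is the RMS
    radial distance from the points to the fitted ellipse.

    Raises
    ------
    ValueError
        For fewer than 6 points, (near-)degenerate input, or a best conic
        that is not an ellipse.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array")
    if pts.shape[0] < 6:
        raise ValueError("ellipse fit requires at least 6 points")
    x, y = pts[:, 0], pts[:, 1]
    # centre and scale for conditioning
    mx, my = x.mean(), y.mean()
    s = max(np.abs(x - mx).max(), np.abs(y - my).max())
    if s <= 0:
        raise ValueError("degenerate input: all points coincide")
    xs, ys = (x - mx) / s, (y - my) / s

    D1 = np.column_stack([xs**2, xs * ys, ys**2])
    D2 = np.column_stack([xs, ys, np.ones_like(xs)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    if np.linalg.cond(S3) > 1e12:
        raise ValueError("degenerate (collinear?) input points")
    T = -np.linalg.solve(S3, S2.T)
    M = S1 + S2 @ T
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    eigval, eigvec = np.linalg.eig(M)
    if np.iscomplexobj(eigval):
        if np.abs(eigval.imag).max() > 1e-8 * max(1.0, np.abs(eigval.real).max()):
            raise ValueError("best-fitting conic is not an ellipse")
        eigval, eigvec = eigval.real, eigvec.real
    cond = 4 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    valid = np.where(cond > 0)[0]
    if valid.size == 0:
        raise ValueError("best-fitting conic is not an ellipse")
    a1 = eigvec[:, valid[np.argmin(np.abs(eigval[valid]))]]
    a2 = T @ a1
    A, B, C = a1
    D, E, F = a2

    # undo the normalisation: x = (X - mx)/s etc.
    A_, B_, C_ = A / s**2, B / s**2, C / s**2
    D_ = D / s - 2 * A_ * mx - B_ * my
    E_ = E / s - 2 * C_ * my - B_ * mx
    F_ = F + A_ * mx**2 + B_ * mx * my + C_ * my**2 - (D / s) * mx - (E / s) * my
    return _conic_to_ellipse(A_, B_, C_, D_, E_, F_, pts)


def _conic_to_ellipse(A, B, C, D, E, F, pts) -> EllipseFit:
    den = 4 * A * C - B**2
    if den <= 0:
        raise ValueError("conic is not an ellipse")
    cx = (B * E - 2 * C * D) / den
    cy = (B * D - 2 * A * E) / den
    # value of the quadratic form at the centre
    Fc = A * cx**2 + B * cx * cy + C * cy**2 + D * cx + E * cy + F
    Q = np.array([[A, B / 2], [B / 2, C]])
    evals, evecs = np.linalg.eigh(Q)
    if np.any(evals * -Fc <= 0):
        raise ValueError("conic is not a real ellipse")
    axes = np.sqrt(-Fc / evals)  # semi-axes along the eigen directions
    order = np.argsort(axes)[::-1]
    a, b = float(axes[order[0]]), float(axes[order[1]])
    major = evecs[:, order[0]]
    orientation = float(math.atan2(major[1], major[0])) % math.pi

    # RMS radial residual: distance along the centre ray
    dx, dy = pts[:, 0] - cx, pts[:, 1] - cy
    ct, st = math.cos(orientation), math.sin(orientation)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    r = np.hypot(dx, dy)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        resid = np.where(scale > 0, r * np.abs(1 - 1 / scale), 0.0)
    rms = float(np.sqrt(np.mean(resid**2)))
    return EllipseFit(
        centre=(float(cx), float(cy)),
        a=a,
        b=b,
        orientation=orientation,
        rms_residual=rms,
    )


def average_tube_geometry(apical_fits: list, basal_fits: list) -> TubeGeometry:
    """Average per-section ellipse fits into one tube geometry."""
    if not apical_fits or not basal_fits:
        raise ValueError("need at least one fit per surface")
    return TubeGeometry(
        a_apical=float(np.mean([f.a for f in apical_fits])),
        b_apical=float(np.mean([f.b for f in apical_fits])),
        a_basal=float(np.mean([f.a for f in basal_fits])),
        b_basal=float(np.mean([f.b for f in basal_fits])),
    )


def local_radius(x: float, geom: TubeGeometry) -> float:
    """Local radius of curvature at relative apical-basal position ``x``.

    Linearly interpolates the averaged apical and basal ellipse semi-axes
    and evaluates the minor-vertex curvature radius a(x)²/b(x).
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError("x must lie in [0, 1]")
    a = geom.a_apical + x * (geom.a_basal - geom.a_apical)
    b = geom.b_apical + x * (geom.b_basal - geom.b_apical)
    return a**2 / b


def event_fold_changes(
    columns: list,
    geom: TubeGeometry,
    interior_only: bool = True,
) -> list:
    """Curvature fold change R2/R1 between consecutive T1 transitions.

    R2 belongs to the more basal transition of each pair, so fold changes
    exceed 1 when the basal side is flatter.  ``n_between`` is the (by
    definition constant) neighbour number of the cell on the segment
    between the two transitions.  With ``interior_only=False`` the boundary
    segments (apical surface → first transition, last transition → basal
    surface) are included as well, using R(0) and R(1) as end radii.

    Returns a list of dicts (cell_id, n_between, x1, x2, R1, R2,
    R2_over_R1).
    """
    out = []
    for col in columns:
        events = detect_t1(col)
        xs = [e.rel_position for e in events]
        if not interior_only:
            xs = [0.0] + xs + [1.0]
        if len(xs) < 2:
            continue
        for x1, x2 in zip(xs, xs[1:]):
            r1, r2 = local_radius(x1, geom), local_radius(x2, geom)
            mid = 0.5 * (x1 + x2)
            n_between = None
            for e in col.entries:  # neighbour count on the segment between
                if x1 < e.z < x2 or abs(e.z - mid) < 1e-12:
                    n_between = len(e.neighbour_ids)
                    break
            if n_between is None:  # transitions at adjacent interfaces
                k = min(
                    range(len(col.entries)),
                    key=lambda i: abs(col.entries[i].z - mid),
                )
                n_between = len(col.entries[k].neighbour_ids)
            out.append(
                {
                    "cell_id": col.cell_id,
                    "n_between": n_between,
                    "x1": float(x1),
                    "x2": float(x2),
                    "R1": float(r1),
                    "R2": float(r2),
                    "R2_over_R1": float(r2 / r1),
                }
            )
    return out


def fold_change_summary(fold_table: list) -> dict:
    """Group fold changes by neighbour number: median, quartiles, mean ± CI."""
    groups: dict = {}
    for row in fold_table:
        groups.setdefault(row["n_between"], []).append(row["R2_over_R1"])
    summary = {}
    for n, vals in sorted(groups.items()):
        v = np.array(vals)
        sem = v.std(ddof=1) / math.sqrt(v.size) if v.size > 1 else 0.0
        summary[n] = {
            "count": int(v.size),
            "median": float(np.median(v)),
            "q25": float(np.percentile(v, 25)),
            "q75": float(np.percentile(v, 75)),
            "mean": float(v.mean()),
            "ci95": (float(v.mean() - 1.96 * sem), float(v.mean() + 1.96 * sem)),
        }
    return summary


# --- neighbour-number-dependent curvature prediction -----------------------

_FOLD_MODELS = {}


def register_fold_model(name: str, fn) -> None:
    """Register an alternative closed form for the predicted fold change."""
    _FOLD_MODELS[name] = fn


def predicted_fold(n: int, model: str = "circumference") -> float:
    """Curvature fold change required for one neighbour gain, by model.

    The default 'circumference' model assumes the neighbour number is
    proportional to the local circumference, so gaining one neighbour
    requires a fold change of (n + 1)/n — strictly decreasing in n, i.e.
    cells with few neighbours need much larger curvature changes per
    transition than cells with many.  This is an explicit modelling
    assumption of this package; alternative closed forms can be plugged in
    via :func:`register_fold_model`.
    """
    if int(n) < 3:
        raise ValueError("n must be >= 3")
    fn = _FOLD_MODELS[model]
    return float(fn(int(n)))


register_fold_model("circumference", lambda n: (n + 1) / n)
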