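"""Nuclear morphometrics and their coupling to cell cross-sections.

Pseudostratified epithelia owe their layered appearance to interkinetic
nuclear migration: nuclei travel along the apical-basal axis with the cell
cycle and divide apically.  Because the nucleus occupies a large fraction
of the cell volume, the cell's cross-sectional area profile along the axis
tracks the nuclear cross-section, which couples nuclear position to the
lateral T1 transitions analysed elsewhere in this package.

Ellipticity is defined as 1 − (shortest / longest principal semi-axis)
derived from the second-moment (inertia) tensor of the nucleus mask: a
sphere scores 0, elongated nuclei score closer to 1.  The definition is
isolated here so an alternative convention can be swapped in one place.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage, stats

from epi3d.datatypes import NuclearMorphometry

__all__ = [
    "nuclear_stats",
    "cell_nucleus_correlation",
    "equivalent_diameters",
    "ellipticity_position_test",
    "ellipticity_from_semi_axes",
]


def ellipticity_from_semi_axes(semi_axes) -> float:
    """1 − shortest/longest principal semi-axis; 0 for a sphere."""
    axes = sorted(float(a) for a in semi_axes)
    if axes[0] <= 0:
        raise ValueError("semi-axes must be positive")
    return 1.0 - axes[0] / axes[-1]


def _connected_3d(mask: np.ndarray, periodic: bool) -> int:
    """Number of 6-connected components, with optional y/x wrap (torus)."""
    comp, ncomp = ndimage.label(mask)
    if ncomp <= 1 or not periodic:
        return ncomp
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

    for edge_a, edge_b in (
        (comp[:, 0, :], comp[:, -1, :]),
        (comp[:, :, 0], comp[:, :, -1]),
    ):
        both = (edge_a > 0) & (edge_b > 0)
        for a, b in zip(edge_a[both].ravel(), edge_b[both].ravel()):
            union(int(a), int(b))
    return len({find(c) for c in range(1, ncomp + 1)})


def nuclear_stats(
    nucleus_labels: np.ndarray,
    voxel_size,
    axis_order: str = "zyx",
    periodic: bool = False,
) -> list:
    """Morphometrics of every labelled nucleus in a 3D label grid.

    Parameters
    ----------
    nucleus_labels
        3D integer array; 0 = background, labels map 1:1 to cell ids.
        First axis is the apical-basal (z) direction by default.
    voxel_size
        Scalar or (z, y, x) voxel edge lengths in µm.

    Principal semi-axes derive from the eigenvalues of the voxel covariance
    matrix: for a solid ellipsoid the covariance eigenvalue along a
    principal axis of semi-length a equals a²/5, so a = √(5λ).

    With ``periodic=True`` the lateral (y, x) axes wrap as a torus —
    the convention of the synthetic generator's label stacks; nuclei
    crossing the seam are unwrapped around their first voxel before
    moments are computed.

    Raises
    ------
    ValueError
        If a nucleus is split into disconnected components.
    """
    labels = np.asarray(nucleus_labels)
    if labels.ndim != 3:
        raise ValueError("nucleus_labels must be 3D")
    if axis_order != "zyx":
        raise ValueError("only 'zyx' axis order is supported")
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy()
    if np.any(vs <= 0):
        raise ValueError("voxel sizes must be positive")
    voxel_volume = float(np.prod(vs))
    n_z = labels.shape[0]
    tissue_height = n_z * vs[0]

    span = np.array(labels.shape) * vs
    out = []
    for lab in np.unique(labels[labels > 0]):
        mask = labels == lab
        ncomp = _connected_3d(mask, periodic)
        if ncomp > 1:
            raise ValueError(f"nucleus label {int(lab)} has {ncomp} components")
        coords = np.argwhere(mask).astype(float)
        coords = (coords + 0.5) * vs  # voxel centres, µm
        if periodic:  # unwrap y, x around the first voxel (minimum image)
            for ax in (1, 2):
                d = coords[:, ax] - coords[0, ax]
                coords[:, ax] = (
                    coords[0, ax] + np.mod(d + span[ax] / 2, span[ax])
                    - span[ax] / 2
                )
        volume = mask.sum() * voxel_volume
        centre = coords.mean(axis=0)
        cov = np.cov(coords.T) if coords.shape[0] > 1 else np.zeros((3, 3))
        evals = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
        semi = tuple(float(np.sqrt(5.0 * v)) for v in evals)
        per_layer = {
            int(zi): float(mask[zi].sum() * vs[1] * vs[2])
            for zi in range(n_z)
            if mask[zi].any()
        }
        out.append(
            NuclearMorphometry(
                cell_id=int(lab),
                volume=float(volume),
                ellipticity=ellipticity_from_semi_axes(
                    [max(s, 1e-9) for s in semi]
                ),
                centre_z=float(centre[0] / tissue_height),
                semi_axes=semi,
                per_layer_area=per_layer,
            )
        )
    return out


def cell_nucleus_correlation(columns: list, nuclei: list):
    """Pearson correlations between cell and nuclear sizes.

    Returns ``(r_volume, r_area, n_volume_pairs, n_area_pairs)``:
    ``r_volume`` over per-cell (cell volume, nuclear volume) pairs, with
    cell volume integrated from the area profile; ``r_area`` over all
    (cell area, nuclear area) section pairs restricted to layers where the
    nucleus is present.
    """
    nuc_by_id = {m.cell_id: m for m in nuclei}
    vol_pairs = []
    area_pairs = []
    for col in columns:
        m = nuc_by_id.get(col.cell_id)
        if m is None:
            continue
        areas = np.array([e.area for e in col.entries])
        zs = np.array([e.z for e in col.entries])
        cell_volume = float(np.trapezoid(areas, zs) * col.height)
        vol_pairs.append((cell_volume, m.volume))
        for e in col.entries:
            if e.nuclear_area is not None and e.nuclear_area > 0:
                area_pairs.append((e.area, e.nuclear_area))
    if len(vol_pairs) < 3 or len(area_pairs) < 3:
        raise ValueError("need at least 3 matched cell-nucleus pairs")
    vp = np.array(vol_pairs)
    ap = np.array(area_pairs)
    r_volume = float(stats.pearsonr(vp[:, 0], vp[:, 1]).statistic)
    r_area = float(stats.pearsonr(ap[:, 0], ap[:, 1]).statistic)
    return r_volume, r_area, len(vol_pairs), len(area_pairs)


def equivalent_diameters(
    cell_volume: float, cell_height: float, nuclear_volume: float
):
    """Idealised diameters: cell as a cylinder, nucleus as a sphere.

    Returns ``(d_cell_cylinder, d_nucleus_sphere)`` for a cylinder of the
    measured cell volume and height and a sphere of the nuclear volume.
    When the spherical nuclear diameter exceeds the cylindrical cell
    diameter, the nucleus must deform to fit inside its cell.
    """
    if cell_volume <= 0 or cell_height <= 0 or nuclear_volume <= 0:
        raise ValueError("volumes and height must be positive")
    d_cell = 2.0 * math.sqrt(cell_volume / (math.pi * cell_height))
    d_nuc = (6.0 * nuclear_volume / math.pi) ** (1.0 / 3.0)
    return d_cell, d_nuc


def ellipticity_position_test(nuclei: list):
    """One-sided Welch t-test: apical nuclei are less elliptic.

    Compares the ellipticity of nuclei centred in the apical quarter
    (centre_z ∈ [0, 0.25], closed interval) against those in the middle
    half (centre_z ∈ (0.25, 0.75]).  Returns ``(t, dof, p_one_sided)``
    with the alternative "apical group has lower ellipticity".
    """
    apical = np.array([m.ellipticity for m in nuclei if m.centre_z <= 0.25])
    middle = np.array(
        [m.ellipticity for m in nuclei if 0.25 < m.centre_z <= 0.75]
    )
    if apical.size < 3 or middle.size < 3:
        raise ValueError("need at least 3 nuclei in each position group")
    res = stats.ttest_ind(apical, middle, equal_var=False, alternative="less")
    # Welch-Satterthwaite degrees of freedom
    va, vm = apical.var(ddof=1), middle.var(ddof=1)
    na, nm = apical.size, middle.size
    if va == 0 and vm == 0:
        return 0.0, float(na + nm - 2), 0.5
    dof = (va / na + vm / nm) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vm / nm) ** 2 / (nm - 1)
    )
    return float(res.statistic), float(dof), float(res.pvalue)
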