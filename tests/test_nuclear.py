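"""Nuclear morphometrics and nucleus–cell coupling."""

import numpy as np
import pytest

from epi3d.datatypes import NuclearMorphometry
from epi3d.nuclear import (
    cell_nucleus_correlation,
    ellipticity_from_semi_axes,
    ellipticity_position_test,
    equivalent_diameters,
    nuclear_stats,
)
from conftest import make_column


def rasterise_ellipsoid(semi_axes, shape=(40, 40, 40), voxel=1.0, label=1):
    """Binary ellipsoid mask centred in a (z, y, x) grid."""
    zz, yy, xx = np.meshgrid(
        *[(np.arange(s) + 0.5) * voxel for s in shape], indexing="ij"
    )
    centre = [s * voxel / 2 for s in shape]
    az, ay, ax = semi_axes
    inside = (
        ((zz - centre[0]) / az) ** 2
        + ((yy - centre[1]) / ay) ** 2
        + ((xx - centre[2]) / ax) ** 2
    ) <= 1.0
    return (inside * label).astype(np.int32)


class TestNuclearStats:
    def test_sphere_has_near_zero_ellipticity(self):
        grid = rasterise_ellipsoid((10, 10, 10))
        (m,) = nuclear_stats(grid, voxel_size=1.0)
        assert m.ellipticity < 0.05
        assert m.volume == pytest.approx(4 / 3 * np.pi * 1000, rel=0.02)
        assert m.centre_z == pytest.approx(0.5, abs=0.02)

    def test_prolate_two_to_one_ellipsoid(self):
        grid = rasterise_ellipsoid((16, 8, 8))
        (m,) = nuclear_stats(grid, voxel_size=1.0)
        assert m.ellipticity == pytest.approx(0.5, abs=0.05)

    def test_rotation_invariance_of_ellipticity(self):
        a = rasterise_ellipsoid((14, 7, 7))
        b = rasterise_ellipsoid((7, 14, 7))  # same shape, axis permuted
        (ma,) = nuclear_stats(a, voxel_size=1.0)
        (mb,) = nuclear_stats(b, voxel_size=1.0)
        assert ma.ellipticity == pytest.approx(mb.ellipticity, abs=0.02)

    def test_semi_axes_recovered_from_inertia_tensor(self):
        grid = rasterise_ellipsoid((12, 9, 6), shape=(40, 40, 40))
        (m,) = nuclear_stats(grid, voxel_size=1.0)
        assert sorted(m.semi_axes) == pytest.approx([6, 9, 12], rel=0.05)

    def test_anisotropic_voxels(self):
        grid = rasterise_ellipsoid((5, 10, 10), shape=(20, 40, 40))
        (m,) = nuclear_stats(grid, voxel_size=(2.0, 1.0, 1.0))
        # 5 voxels × 2 µm = 10 µm: physically a sphere
        assert m.ellipticity < 0.05

    def test_split_nucleus_rejected(self):
        grid = np.zeros((10, 10, 10), dtype=np.int32)
        grid[1, 1, 1] = 3
        grid[8, 8, 8] = 3
        with pytest.raises(ValueError, match="label 3"):
            nuclear_stats(grid, voxel_size=1.0)

    def test_per_layer_areas_reported(self):
        grid = rasterise_ellipsoid((6, 6, 6), shape=(20, 20, 20))
        (m,) = nuclear_stats(grid, voxel_size=1.0)
        assert m.per_layer_area
        assert max(m.per_layer_area.values()) == pytest.approx(
            np.pi * 36, rel=0.1
        )


class TestCellNucleusCorrelation:
    def _columns_and_nuclei(self, vol_fn, rng=None, n=50):
        cols, nuclei = [], []
        base = np.linspace(200, 900, n)
        for i, vc in enumerate(base, start=1):
            area = vc / 25.0
            cols.append(
                make_column(
                    [{1, 2, 3}] * 5,
                    areas=[area] * 5,
                    nuclear_areas=[None, area / 2, area / 2, area / 2, None],
                    cell_id=i,
                )
            )
            nuclei.append(
                NuclearMorphometry(
                    cell_id=i,
                    volume=vol_fn(vc, rng),
                    ellipticity=0.3,
                    centre_z=0.5,
                    semi_axes=(3, 3, 5),
                )
            )
        return cols, nuclei

    def test_perfect_linear_relationship(self):
        cols, nuclei = self._columns_and_nuclei(lambda vc, _: 0.5 * vc)
        r_vol, r_area, n_vol, n_area = cell_nucleus_correlation(cols, nuclei)
        assert r_vol == pytest.approx(1.0)
        assert r_area == pytest.approx(1.0)
        assert n_vol == 50

    def test_independent_volumes_uncorrelated(self):
        rng = np.random.default_rng(0)
        cols, nuclei = self._columns_and_nuclei(
            lambda vc, r: r.uniform(100, 500), rng=rng, n=200
        )
        r_vol, _, _, _ = cell_nucleus_correlation(cols, nuclei)
        assert abs(r_vol) < 0.15

    def test_generated_tissue_strongly_coupled(self, default_tissue):
        morph = [
            NuclearMorphometry(
                cell_id=n.cell_id,
                volume=n.volume,
                ellipticity=ellipticity_from_semi_axes(n.semi_axes),
                centre_z=n.centre_z,
                semi_axes=n.semi_axes,
            )
            for n in default_tissue.nuclei
        ]
        r_vol, r_area, _, _ = cell_nucleus_correlation(
            default_tissue.columns, morph
        )
        assert r_area > 0.7
        assert r_vol > 0.7

    def test_too_few_pairs_rejected(self):
        cols, nuclei = self._columns_and_nuclei(lambda vc, _: vc, n=2)
        with pytest.raises(ValueError):
            cell_nucleus_correlation(cols, nuclei)


class TestEquivalentDiameters:
    def test_unit_sphere_and_cylinder(self):
        d_cell, d_nuc = equivalent_diameters(np.pi, 1.0, np.pi / 6)
        assert d_cell == pytest.approx(2.0)
        assert d_nuc == pytest.approx(1.0)

    def test_lung_scale_nucleus_outgrows_cell_diameter(self):
        # a 600 µm³ cell of height 25 µm vs a nucleus at 55% of its volume
        d_cell, d_nuc = equivalent_diameters(600.0, 25.0, 0.55 * 600.0)
        assert d_nuc > d_cell

    def test_homogeneous_scaling(self):
        d_cell, d_nuc = equivalent_diameters(400.0, 20.0, 150.0)
        k = 1.7
        d_cell_k, d_nuc_k = equivalent_diameters(
            400.0 * k**3, 20.0 * k, 150.0 * k**3
        )
        assert d_cell_k == pytest.approx(k * d_cell)
        assert d_nuc_k == pytest.approx(k * d_nuc)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            equivalent_diameters(0.0, 25.0, 300.0)


def nuc(ell, z, cid):
    return NuclearMorphometry(
        cell_id=cid, volume=300.0, ellipticity=ell, centre_z=z,
        semi_axes=(3, 3, 5),
    )


class TestEllipticityPositionTest:
    def test_identical_groups(self):
        nuclei = [nuc(0.4, 0.1, i) for i in range(5)] + [
            nuc(0.4, 0.5, 10 + i) for i in range(5)
        ]
        t, dof, p = ellipticity_position_test(nuclei)
        assert t == 0.0
        assert p == 0.5

    def test_reduced_apical_ellipticity_detected(self):
        rng = np.random.default_rng(1)
        nuclei = [
            nuc(rng.normal(0.2, 0.1), rng.uniform(0, 0.25), i)
            for i in range(30)
        ] + [
            nuc(rng.normal(0.5, 0.1), rng.uniform(0.3, 0.75), 100 + i)
            for i in range(30)
        ]
        _, _, p = ellipticity_position_test(nuclei)
        assert p < 0.001

    def test_swapped_effect_direction(self):
        rng = np.random.default_rng(2)
        nuclei = [
            nuc(rng.normal(0.5, 0.1), rng.uniform(0, 0.25), i)
            for i in range(30)
        ] + [
            nuc(rng.normal(0.2, 0.1), rng.uniform(0.3, 0.75), 100 + i)
            for i in range(30)
        ]
        _, _, p = ellipticity_position_test(nuclei)
        assert p > 0.5

    def test_boundary_nucleus_goes_to_apical_group(self):
        # centre_z exactly 0.25 belongs to the apical (closed) interval
        nuclei = [nuc(0.1, 0.25, 1), nuc(0.1, 0.2, 2), nuc(0.1, 0.1, 3)]
        nuclei += [nuc(0.5, 0.5, 4), nuc(0.5, 0.6, 5), nuc(0.5, 0.7, 6)]
        _, _, p = ellipticity_position_test(nuclei)
        assert p < 0.5  # apical group complete, effect detected

    def test_empty_group_rejected(self):
        nuclei = [nuc(0.4, 0.5, i) for i in range(6)]
        with pytest.raises(ValueError):
            ellipticity_position_test(nuclei)


def test_ellipticity_definition():
    assert ellipticity_from_semi_axes((5, 5, 5)) == 0.0
    assert ellipticity_from_semi_axes((2, 4, 4)) == pytest.approx(0.5)
    assert 0 <= ellipticity_from_semi_axes((1, 2, 10)) < 1
    with pytest.raises(ValueError):
        ellipticity_from_semi_axes((0, 1, 2))


def test_generated_tissue_volume_fraction_roundtrip(default_tissue):
    ratios = []
    nuc_by_id = {n.cell_id: n for n in default_tissue.nuclei}
    for col in default_tissue.columns:
        areas = np.array([e.area for e in col.entries])
        zs = np.array([e.z for e in col.entries])
        cell_vol = np.trapezoid(areas, zs) * col.height
        ratios.append(nuc_by_id[col.cell_id].volume / cell_vol)
    target = default_tissue.config.nuclear_volume_fraction
    assert abs(np.mean(ratios) - target) <= 0.1
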