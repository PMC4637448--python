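"""Voxel geometry builders: node-count conventions, analytic-volume oracles,
labelling and connectivity invariants."""
import numpy as np
import pytest

from atriadrift.geometry import (LABELS, VoxelGeometry, build_pm1, build_pm2,
                                 build_pm3, build_ridge, build_sheet2d,
                                 build_strand1d, build_wedge)

DX = 0.33


@pytest.fixture(scope="module")
def pm1():
    return build_pm1(dx=DX)


@pytest.fixture(scope="module")
def pm2():
    return build_pm2(dx=DX)


@pytest.fixture(scope="module")
def pm3():
    return build_pm3(dx=DX)


class TestSheetAndStrand:
    def test_sheet_node_counts(self):
        g = build_sheet2d(25.0, 25.0, DX)
        assert g.shape == (77, 77, 1)          # round(25/0.33) + 1 per side
        assert g.mask.all()
        assert g.epi.all()
        assert (g.labels == LABELS["wall"]).all()

    def test_sheet_degenerate(self):
        g = build_sheet2d(DX, DX, DX)
        assert g.shape == (2, 2, 1)

    def test_strand_counts(self):
        g = build_strand1d(33.0, DX)
        assert g.shape == (101, 1, 1)
        assert g.n_tissue // 2 == 50           # mid-node convention

    def test_strand_degenerate_and_warning(self):
        with pytest.warns(UserWarning):
            g = build_strand1d(DX, DX)
        assert g.n_tissue == 2


class TestWedge:
    def test_thick_end_layers(self):
        g = build_wedge(dx=DX)
        assert int(g.mask[0, 0, :].sum()) == 9     # round(3 mm / 0.33 mm)

    def test_volume_oracle(self):
        g = build_wedge(dx=DX)
        expect = 0.5 * 25.0 * 25.0 * 3.0 / DX ** 3
        assert g.n_tissue == pytest.approx(expect, rel=0.05)

    def test_taper_monotone_and_connected(self):
        g = build_wedge(dx=DX)
        layers = g.mask.sum(axis=2)[:, 0]
        assert np.all(np.diff(layers) <= 0)
        assert layers[-1] >= 1                     # monolayer retained
        assert g.n_components() == 1

    def test_monolayer_degenerate(self):
        g = build_wedge(max_thickness=2 * DX, dx=DX)
        assert g.mask[:, :, 0].all()

    def test_refinement_improves_volume_agreement(self):
        exact = 0.5 * 25.0 * 25.0 * 3.0
        errs = []
        for dx in (0.33, 0.15):
            g = build_wedge(dx=dx)
            errs.append(abs(g.n_tissue * dx ** 3 - exact) / exact)
        assert errs[1] < errs[0]

    def test_mirror_symmetry_in_y(self):
        g = build_wedge(dx=DX)
        assert np.array_equal(g.mask, g.mask[:, ::-1, :])


class TestRidge:
    def test_zero_height_is_plain_slab(self):
        g0 = build_ridge(ridge_height=0.0, dx=DX)
        assert (g0.labels[g0.mask] == LABELS["wall"]).all()
        assert g0.shape[2] == 9

    def test_layers_under_strip(self):
        g = build_ridge(dx=DX)
        centre = g.shape[0] // 2
        assert int(g.mask[centre, 0, :].sum()) in (15, 16)   # 5 mm total

    def test_ridge_volume_oracle(self):
        g = build_ridge(dx=DX)
        n_ridge = int((g.labels == LABELS["ridge"]).sum())
        assert n_ridge == pytest.approx(2.0 * 2.0 * 25.0 / DX ** 3, rel=0.10)

    def test_mirror_symmetry(self):
        """Invariant under y-mirror exactly; under x-mirror up to the single
        voxel-column offset of centring an even-width strip on an odd grid."""
        g = build_ridge(dx=DX)
        assert np.array_equal(g.mask, g.mask[:, ::-1, :])
        flipped = g.mask[::-1, :, :]
        assert (np.array_equal(g.mask, flipped)
                or np.array_equal(g.mask[1:], flipped[:-1])
                or np.array_equal(g.mask[:-1], flipped[1:]))

    def test_ridge_wider_than_wall_rejected(self):
        with pytest.raises(ValueError):
            build_ridge(ridge_width=30.0, dx=DX)


class TestPM1:
    def test_two_junction_clusters(self, pm1):
        assert len(pm1.junction_clusters()) == 2

    def test_chord_matches_semicircle(self, pm1):
        """Junction separation = semicircle chord 2L/pi ~ 8.9 mm."""
        cl = pm1.junction_clusters()
        c0 = cl[0].mean(axis=0) * DX
        c1 = cl[1].mean(axis=0) * DX
        chord = np.linalg.norm(c1 - c0)
        assert chord == pytest.approx(2 * 14.0 / np.pi, abs=1.0)

    def test_bridge_shortcut_property(self, pm1):
        """PM1's defining feature: the along-wall junction distance is
        noticeably shorter than the 14 mm bridge."""
        cl = pm1.junction_clusters()
        wall_dist = np.linalg.norm((cl[1].mean(0) - cl[0].mean(0)) * DX)
        assert wall_dist < 14.0 - 2.0

    def test_bridge_arc_height(self, pm1):
        """The semicircular arc rises ~ its radius (14/pi) above the wall."""
        bridge = np.argwhere((pm1.labels == LABELS["bridge"])
                             | (pm1.labels == LABELS["junction"]))
        z_top_wall = 8 * DX
        rise = bridge[:, 2].max() * DX - z_top_wall
        assert rise == pytest.approx(14.0 / np.pi + 1.0, abs=1.0)

    def test_connected(self, pm1):
        assert pm1.n_components() == 1


class TestPM2PM3:
    def test_geodesic_longer_than_bridge(self, pm2):
        """On the endocardial sphere the along-wall path between the
        junctions exceeds the 8 mm straight bridge (bridge = short cut)."""
        geo = pm2.meta["geodesic_j1j2"]
        r_in, r_ax = 12.0, 12.0 - 2.0          # wall radius, bridge-axis radius
        assert geo == pytest.approx(
            2 * r_in * np.arcsin(8.0 / (2 * r_ax)), rel=1e-6)
        assert geo > 8.0

    def test_bridge_clear_of_wall_midspan(self, pm2):
        """Away from the junction feet the free span does not touch the
        wall: only two junction clusters exist and mid-span voxels keep the
        plain bridge label."""
        bridge = np.argwhere(pm2.labels == LABELS["bridge"])
        assert bridge.size > 0
        pos = bridge * DX + np.asarray(pm2.origin)
        # voxels near the mid-span plane x ~ 0
        mid = pos[np.abs(pos[:, 0]) < 1.0]
        assert mid.shape[0] > 0

    def test_shell_volume_oracle(self, pm2):
        n_wall = int((pm2.labels == LABELS["wall"]).sum())
        expect = 2 * np.pi * (15.0 ** 3 - 12.0 ** 3) / 3.0 / DX ** 3
        assert n_wall == pytest.approx(expect, rel=0.10)

    def test_pm2_junctions(self, pm2):
        assert len(pm2.junction_clusters()) == 2

    def test_pm3_minus_ridge_is_pm2(self, pm2, pm3):
        stripped = pm3.mask & ~(pm3.labels == LABELS["ridge"])
        assert np.array_equal(stripped, pm2.mask)

    def test_pm3_ridge_attached_along_wall(self, pm3):
        """Every ridge voxel is within one voxel of the wall (the ridge runs
        on the endocardial surface) and the geometry stays one component."""
        from scipy import ndimage

        ridge = pm3.labels == LABELS["ridge"]
        assert ridge.sum() > 0
        wall = pm3.labels == LABELS["wall"]
        # the 1 mm-radius tube extends up to ~3 voxels off the wall surface
        near = ndimage.binary_dilation(
            wall, structure=ndimage.generate_binary_structure(3, 3),
            iterations=3)
        assert (near | ~ridge).all()
        assert pm3.n_components() == 1

    def test_epi_is_convex_face(self, pm2):
        idx = np.argwhere(pm2.epi)
        pos = idx * DX + np.asarray(pm2.origin)
        r = np.linalg.norm(pos, axis=1)
        assert np.all(r >= 15.0 - 3 * DX)


class TestValidation:
    def test_junction_labelling_consistency(self, pm1):
        from scipy import ndimage

        bridgeish = (pm1.labels == LABELS["bridge"]) \
            | (pm1.labels == LABELS["junction"])
        wallish = pm1.labels == LABELS["wall"]
        near_wall = ndimage.binary_dilation(
            wallish, ndimage.generate_binary_structure(3, 1))
        junction = pm1.labels == LABELS["junction"]
        assert np.array_equal(junction, bridgeish & near_wall)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_sheet2d(-1.0, 25.0, DX)
        with pytest.raises(ValueError):
            VoxelGeometry(np.ones((4, 4, 4), bool), dx=-0.1)
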