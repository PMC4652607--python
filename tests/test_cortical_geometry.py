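import numpy as np
import pytest
from scipy import ndimage

from osteomorph.core import VoxelVolume
from osteomorph.cortical_geometry import (degree_of_anisotropy,
                                          local_thickness_3d,
                                          local_thickness_map, slice_geometry,
                                          tmd_apply, tmd_calibrate,
                                          whole_bone_profile)
from osteomorph.synthetic_data import (make_ball, make_cortical_shell,
                                       make_hollow_cylinder, make_slab)


def _annulus(R=50, r=40):
    return make_hollow_cylinder(R, r, 1)[0]


class TestSliceGeometry:
    def test_annulus_closed_forms(self):
        g = slice_geometry(_annulus(), voxel_size=1000.0)  # 1 voxel = 1 mm
        assert g.csa_mm2 == pytest.approx(900 * np.pi, rel=0.01)
        i_ref = np.pi * (50**4 - 40**4) / 4
        assert g.imin_mm4 == pytest.approx(i_ref, rel=0.02)
        assert g.imax_mm4 == pytest.approx(i_ref, rel=0.02)
        assert g.eccentricity <= 0.05
        assert g.total_porosity_pct == pytest.approx(0.0, abs=1e-9)

    def test_rectangle_closed_forms(self):
        rect = np.zeros((20, 60), dtype=bool)
        rect[5:15, 10:50] = True                 # 10 (y) x 40 (x)
        g = slice_geometry(rect, voxel_size=1000.0)
        assert g.imin_mm4 == pytest.approx(40 * 10**3 / 12, rel=0.02)
        assert g.imax_mm4 == pytest.approx(10 * 40**3 / 12, rel=0.02)
        assert g.csa_mm2 == 400.0

    def test_wall_thickness_2d(self):
        g = slice_geometry(_annulus(50, 40), voxel_size=1000.0)
        assert g.ct_th_2d_mm == pytest.approx(10.0, abs=1.0)

    def test_polar_moment_rotation_invariant(self):
        rect = np.zeros((200, 200), dtype=bool)
        rect[80:120, 50:150] = True              # 40 x 100, well resolved
        base = slice_geometry(rect, 1000.0).polar_mmi_mm4
        for angle in range(15, 90, 15):
            rot = ndimage.rotate(rect.astype(float), angle, reshape=False,
                                 order=1) >= 0.5
            g = slice_geometry(rot, 1000.0)
            assert g.polar_mmi_mm4 == pytest.approx(base, rel=0.02)

    def test_empty_slice_errors(self):
        with pytest.raises(ValueError, match="empty"):
            slice_geometry(np.zeros((5, 5), dtype=bool), 5.0)

    def test_intracortical_pores_raise_total_porosity(self):
        ann = _annulus(30, 20).copy()
        ann[7:11, 31:35] = False                 # small pore in the wall
        g = slice_geometry(ann, 1000.0)
        expected = 100 * 16 / (np.pi * (30**2 - 20**2))
        assert g.total_porosity_pct == pytest.approx(expected, rel=0.1)


class TestWholeBoneProfile:
    def test_straight_shell_flat_profile(self):
        vol, truth = make_cortical_shell(100, 50, 40, voxel_size=1000.0)
        prof = whole_bone_profile(vol, stations=[10, 50, 90])
        assert np.allclose(prof["csa_mm2"], truth["csa_vox2"][0], rtol=0.01)
        assert np.allclose(prof["imin_mm4"], truth["imin_vox4"][0], rtol=0.02)

    def test_tapering_shell_tracks_analytic_csa(self):
        outer = np.linspace(50, 30, 200)
        vol, truth = make_cortical_shell(200, outer, outer - 12,
                                         voxel_size=1000.0)
        prof = whole_bone_profile(vol)
        for _, row in prof.iterrows():
            k = int(row["slice_index"])
            assert row["csa_mm2"] == pytest.approx(truth["csa_vox2"][k],
                                                   rel=0.02)

    def test_station_outside_window_rejected(self):
        vol, _ = make_cortical_shell(50, 20, 15, voxel_size=5.0)
        with pytest.raises(ValueError, match=r"\[10, 90\]"):
            whole_bone_profile(vol, stations=[5])


class TestLocalThickness:
    def test_slab_thickness_exact(self):
        _, mean = local_thickness_3d(make_slab(12), 1.0)
        assert mean == pytest.approx(12.0, abs=1.0)

    def test_hollow_cylinder_wall(self):
        _, mean = local_thickness_3d(make_hollow_cylinder(30, 20, 40), 1.0)
        assert mean == pytest.approx(10.0, abs=1.0)

    def test_sphere_against_brute_force_oracle(self):
        mask = make_ball(4.5)
        # brute force: thickness(x) = 2 max{dt(c) : |x-c| <= dt(c)}
        dt = ndimage.distance_transform_edt(mask)
        pts = np.argwhere(mask)
        dts = dt[mask]
        diff = pts[:, None, :] - pts[None, :, :]
        within = (diff**2).sum(-1) <= dts[None, :]**2
        oracle = 2 * np.where(within, dts[None, :], 0).max(axis=1)
        measured = local_thickness_map(mask)[mask]
        assert measured.mean() == pytest.approx(oracle.mean(), rel=0.10)
        assert np.all(np.abs(measured - oracle) <= 1.0 + 1e-9)

    @pytest.mark.parametrize("d", [16, 22])
    def test_sphere_diameter_within_10pct(self, d):
        _, mean = local_thickness_3d(make_ball(d / 2), 1.0)
        assert mean == pytest.approx(d, rel=0.10)


class TestAnisotropy:
    def _vol(self, mask):
        return VoxelVolume(mask.astype(np.uint8), 1.0, is_binary=True)

    def _isotropic(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((64, 64, 64), dtype=bool)
        zz, yy, xx = np.ogrid[:64, :64, :64]
        for _ in range(150):
            c = rng.integers(6, 58, 3)
            r = int(rng.integers(3, 6))
            mask |= ((zz - c[0])**2 + (yy - c[1])**2 + (xx - c[2])**2) <= r * r
        return mask

    def test_isotropic_medium_low_da(self):
        da = degree_of_anisotropy(self._vol(self._isotropic()), seed=1)
        assert da <= 0.15

    def test_parallel_plates_high_da(self):
        plates = np.zeros((64, 64, 64), dtype=bool)
        plates[::8] = True
        da = degree_of_anisotropy(self._vol(plates), seed=1)
        assert da >= 0.5
        assert da > degree_of_anisotropy(self._vol(self._isotropic()), seed=1)

    def test_deterministic_under_seed(self):
        v = self._vol(self._isotropic())
        assert degree_of_anisotropy(v, seed=7) == degree_of_anisotropy(v, seed=7)


class TestTmdCalibration:
    def test_two_point_line_reproduces_phantoms(self):
        line = tmd_calibrate((100.0, 300.0), (0.25, 0.75))
        assert tmd_apply(line, 100.0) == pytest.approx(0.25)
        assert tmd_apply(line, 300.0) == pytest.approx(0.75)
        assert tmd_apply(line, 200.0) == pytest.approx(0.50)

    def test_equal_attenuations_error(self):
        with pytest.raises(ValueError, match="distinct"):
            tmd_calibrate((150.0, 150.0), (0.25, 0.75))

    def test_inverted_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            tmd_calibrate((300.0, 100.0), (0.25, 0.75))

    def test_three_collinear_phantoms_zero_residual(self):
        line = tmd_calibrate((120.0, 520.0), (0.25, 0.75))
        for atten in (120.0, 320.0, 520.0):
            expected = 0.25 + (atten - 120.0) / 400.0 * 0.5
            assert tmd_apply(line, atten) == pytest.approx(expected, abs=1e-12)
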