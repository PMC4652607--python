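import networkx as nx
import numpy as np
import pytest
from skimage.measure import euler_number

from osteomorph.synthetic_data import (CohortSpec, PlantedPoreSpec,
                                       make_ball, make_cortical_shell,
                                       make_phantoms, make_porous_shell,
                                       make_solid_torus,
                                       make_trabecular_lattice, plant_pores,
                                       simulate_cohort)


class TestCorticalShell:
    def test_straight_annulus_analytic_truth(self):
        vol, truth = make_cortical_shell(100, 50, 40, voxel_size=5.0)
        assert np.allclose(truth["csa_vox2"], np.pi * (50**2 - 40**2))
        assert np.allclose(truth["imin_vox4"], np.pi * (50**4 - 40**4) / 4)
        # rasterized area tracks the analytic annulus closely
        per_slice = vol.data.sum(axis=(1, 2))
        assert np.allclose(per_slice, truth["csa_vox2"], rtol=0.01)

    def test_tapering_outer_radius_monotone_csa(self):
        outer = np.linspace(50, 30, 80)
        _, truth = make_cortical_shell(80, outer, 20, voxel_size=5.0)
        assert (np.diff(truth["csa_vox2"]) < 0).all()

    def test_crossing_profiles_rejected(self):
        with pytest.raises(ValueError, match="outer > inner"):
            make_cortical_shell(10, 30, 35)


class TestPlantPores:
    def _shell(self):
        return make_cortical_shell(80, 40, 15, voxel_size=0.6)[0]

    def test_lacuna_analytic_volume_and_class(self):
        spec = PlantedPoreSpec("lacuna", (40, 30, 60), radii_um=(9, 5, 3))
        assert spec.analytic_volume_um3() == pytest.approx(4 / 3 * np.pi * 135)
        assert spec.target_class() == "lacuna"

    def test_canal_analytic_volume_and_class(self):
        spec = PlantedPoreSpec("canal", (40, 30, 60), radius_um=4.0,
                               length_um=40.0)
        assert spec.analytic_volume_um3() == pytest.approx(np.pi * 16 * 40)
        assert spec.target_class() == "canal"

    def test_single_voxel_speckle_is_noise(self):
        spec = PlantedPoreSpec("noise", (40, 30, 60), radius_um=0.15)
        assert spec.analytic_volume_um3() < 13
        assert spec.target_class() == "noise"

    def test_planting_carves_and_manifests(self):
        shell = self._shell()
        specs = [PlantedPoreSpec("lacuna", (40.0, 16.0, 43.0), radii_um=(6, 4, 2))]
        vol, manifest = plant_pores(shell, specs)
        carved = int(shell.data.sum() - vol.data.sum())
        assert carved == manifest.loc[0, "n_voxels"] > 0
        assert manifest.loc[0, "target_class"] == "lacuna"

    def test_overlapping_pores_error_names_index(self):
        shell = self._shell()
        specs = [
            PlantedPoreSpec("lacuna", (40.0, 16.0, 43.0), radii_um=(6, 4, 2)),
            PlantedPoreSpec("lacuna", (40.0, 17.0, 44.0), radii_um=(6, 4, 2)),
        ]
        with pytest.raises(ValueError, match="spec 1"):
            plant_pores(shell, specs)

    def test_wall_breach_error(self):
        shell = self._shell()
        # centered in the marrow cavity, not in the wall
        specs = [PlantedPoreSpec("lacuna", (40.0, 48.0, 48.0), radii_um=(6, 4, 2))]
        with pytest.raises(ValueError, match="breaches"):
            plant_pores(shell, specs)

    def test_manifest_class_agrees_with_analytic_rederivation(self):
        _, manifest, specs = make_porous_shell(seed=2, n_lacunae=10, n_canals=2,
                                               n_noise=5)
        for _, row in manifest.iterrows():
            v = row["analytic_volume_um3"]
            expected = "noise" if v < 13 else "canal" if v > 1500 else "lacuna"
            assert row["target_class"] == expected


@pytest.mark.parametrize("radius,rtol", [(6, 0.05), (12, 0.02)])
def test_rasterized_sphere_volume_converges(radius, rtol):
    vol = make_ball(radius).sum()
    assert vol == pytest.approx(4 / 3 * np.pi * radius**3, rel=rtol)


class TestTrabecularLattice:
    def test_beta1_matches_graph_cycle_rank(self):
        vol, truth = make_trabecular_lattice(n_cells=(2, 2, 2))
        g = nx.grid_graph(dim=(3, 3, 3))  # independent lattice-graph oracle
        cycle_rank = g.number_of_edges() - g.number_of_nodes() + 1
        assert truth["beta1"] == cycle_rank
        assert truth["euler"] == 1 - cycle_rank
        assert euler_number(vol.mask(), connectivity=3) == truth["euler"]

    def test_rasterized_bvtv_matches_analytic(self):
        vol, truth = make_trabecular_lattice()
        measured = vol.mask().mean()
        assert measured == pytest.approx(truth["bvtv"], rel=0.05)

    def test_single_rod_is_contractible(self):
        rod = np.zeros((30, 9, 9), dtype=bool)
        rod[2:28, 3:6, 3:6] = True
        assert euler_number(rod, connectivity=3) == 1

    def test_solid_torus_has_euler_zero(self):
        assert euler_number(make_solid_torus(10, 4), connectivity=3) == 0

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            make_trabecular_lattice(spacing_um=50, rod_thickness_um=60)


class TestPhantoms:
    def test_identity_map_zero_noise_exact_means(self):
        vols, truth = make_phantoms((0.25, 0.75), attenuation_slope=1.0,
                                    attenuation_intercept=0.0, noise_sd=0.0)
        means = [float(v.data[v.meta["interior_mask"]].mean()) for v in vols]
        assert means == pytest.approx([0.25, 0.75])

    def test_noisy_mean_within_clt_bound(self):
        vols, truth = make_phantoms((0.5,), noise_sd=5.0, seed=3,
                                    radius_vox=20, length=40)
        v = vols[0]
        interior = v.meta["interior_mask"]
        n = int(interior.sum())
        assert n >= 10_000
        assert abs(float(v.data[interior].mean()) - truth["true_means"][0]) \
            <= 3 * 5.0 / np.sqrt(n)

    def test_empty_density_list_error(self):
        with pytest.raises(ValueError):
            make_phantoms(())


class TestSimulateCohort:
    def test_same_seed_identical_table(self):
        a = simulate_cohort(CohortSpec(seed=9))
        b = simulate_cohort(CohortSpec(seed=9))
        assert a.equals(b)

    def test_null_group_means_within_clt_bounds(self):
        t = simulate_cohort(CohortSpec(mu=10.0, sigma=1.0, n_per_group=30,
                                       seed=4))
        for _, grp in t.groupby(["genotype", "age"]):
            assert abs(grp["value"].mean() - 10.0) <= 3 / np.sqrt(len(grp))

    def test_genotype_contrast_recovered(self):
        spec = CohortSpec(genotype_effect=-2.0, n_per_group=6, seed=5)
        t = simulate_cohort(spec)
        contrast = (t[t.genotype == "KO"]["value"].mean()
                    - t[t.genotype == "WT"]["value"].mean())
        assert contrast == pytest.approx(-2.0, abs=3 / np.sqrt(6 * 4))

    def test_n_overrides_unbalance(self):
        spec = CohortSpec(n_overrides=((("WT", 34), 5), (("KO", 34), 5)))
        t = simulate_cohort(spec)
        counts = t.groupby(["genotype", "age"]).size()
        assert counts[("WT", 34)] == 5 and counts[("WT", 5)] == 6

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_per_group=1)
        with pytest.raises(ValueError):
            CohortSpec(sigma=0.0)
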