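"""Generator properties: mesh topology, determinism, parcellation coverage,
noise calibration, phantom construction, and contact geometry."""

import numpy as np
import pytest

from zmapsoz.destrieux import load_destrieux_lobe_table
from zmapsoz.preproc import AffineTransform, gaussian_smooth_volume, ncc
from zmapsoz.synthetic import (
    CONTACT_PITCH_MM,
    SimulationConfig,
    make_parcellation,
    make_toy_surface,
    simulate_contacts,
    simulate_control_cohort,
    simulate_patient,
    simulate_volume_scene,
)


class TestToySurface:
    @pytest.mark.parametrize("subdiv,expected", [(1, 42), (2, 162), (3, 642)])
    def test_icosphere_vertex_count(self, subdiv, expected):
        s = make_toy_surface(subdiv, seed=0)
        assert s.n_vertices == expected == 10 * 4**subdiv + 2

    def test_closed_manifold(self):
        s = make_toy_surface(3, seed=0)
        assert s.euler_characteristic() == 2
        # every edge shared by exactly 2 faces
        f = s.faces
        edges = np.sort(
            np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        assert np.all(counts == 2)

    def test_outward_unit_normals_and_thickness_range(self):
        s = make_toy_surface(3, seed=1)
        assert np.allclose(np.linalg.norm(s.normals, axis=1), 1.0)
        center = s.vertices.mean(axis=0)
        assert np.all(np.einsum("ij,ij->i", s.normals, s.vertices - center) > 0)
        assert s.thickness.min() >= 1.5 and s.thickness.max() <= 4.5

    def test_same_seed_bit_identical(self):
        a = make_toy_surface(3, seed=7)
        b = make_toy_surface(3, seed=7)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.thickness, b.thickness)


class TestParcellation:
    def test_partition_covers_all_vertices(self):
        s = make_toy_surface(3, seed=0)
        p = make_parcellation(s, 10, seed=0)
        assert len(p.labels) == 642
        assert set(np.unique(p.labels)) == set(range(1, 11))

    def test_regions_pairwise_disjoint_and_exhaustive(self):
        s = make_toy_surface(3, seed=2)
        p = make_parcellation(s, 8, seed=2)
        union = np.concatenate([p.vertices_of(i) for i in p.region_ids])
        assert len(union) == len(set(union)) == s.n_vertices

    def test_regions_edge_connected(self):
        from scipy.sparse import csgraph

        s = make_toy_surface(2, seed=0)
        p = make_parcellation(s, 6, seed=0)
        adj = s.adjacency
        for rid in p.region_ids:
            verts = p.vertices_of(rid)
            sub = adj[verts][:, verts]
            n_comp, _ = csgraph.connected_components(sub)
            assert n_comp == 1

    def test_deterministic(self):
        s = make_toy_surface(3, seed=0)
        a = make_parcellation(s, 12, seed=5)
        b = make_parcellation(s, 12, seed=5)
        assert np.array_equal(a.labels, b.labels)

    def test_all_five_lobes_present(self, parcellation):
        assert set(parcellation.region_table["lobe"]) == {
            "frontal", "parietal", "temporal", "occipital", "insular",
        }


class TestDestrieuxLookup:
    def test_region_and_lobe_counts(self):
        table = load_destrieux_lobe_table()
        assert len(table) == 74
        counts = {l: sum(1 for v in table.values() if v == l) for l in set(table.values())}
        assert counts == {
            "frontal": 28, "parietal": 11, "temporal": 14, "occipital": 13, "insular": 8,
        }


class TestControlCohort:
    def test_zero_noise_gives_identical_baseline_maps(self, surface_pair, parcellation):
        cfg = SimulationConfig(seed=0, control_noise_sd=0.0)
        maps = simulate_control_cohort(surface_pair, parcellation, cfg, n_controls=3)
        assert np.array_equal(maps[0], maps[1]) and np.array_equal(maps[1], maps[2])

    def test_vertex_noise_sd_matches_configuration(self, surface_pair, parcellation):
        """Sample SD over many simulated controls reproduces the configured
        fraction-of-baseline noise model within 3 % at every vertex."""
        from zmapsoz.synthetic import control_baseline

        cfg = SimulationConfig(seed=42, control_noise_sd=0.05, mesh_subdivisions=2)
        from zmapsoz.synthetic import make_surface_pair, make_parcellation_pair

        pair = make_surface_pair(2, seed=42)
        parc = make_parcellation_pair(pair, 6, seed=42)
        maps = simulate_control_cohort(pair, parc, cfg, n_controls=10_000)
        sd = np.vstack(maps).std(axis=0, ddof=1)
        expected = cfg.control_noise_sd * control_baseline(pair, parc, cfg)
        assert np.all(np.abs(sd / expected - 1.0) < 0.03)

    def test_same_seed_identical_cohort(self, surface_pair, parcellation, sim_config):
        a = simulate_control_cohort(surface_pair, parcellation, sim_config, n_controls=3)
        b = simulate_control_cohort(surface_pair, parcellation, sim_config, n_controls=3)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestPatient:
    def test_planted_regions_recorded(self, surface_pair, parcellation, sim_config):
        _, truth = simulate_patient(surface_pair, parcellation, [3, 15], -3.0, sim_config)
        assert truth.soz_region_ids == {3, 15}
        assert truth.soz_regions == {parcellation.key_of(3), parcellation.key_of(15)}

    def test_unknown_region_rejected(self, surface_pair, parcellation, sim_config):
        with pytest.raises(KeyError):
            simulate_patient(surface_pair, parcellation, [999], -3.0, sim_config)

    def test_planted_effect_size_calibration(self, surface_pair, parcellation):
        """Mean planted deviation in control-SD units converges to the
        configured lesion effect (Monte-Carlo over replicates)."""
        from zmapsoz.synthetic import control_baseline

        cfg = SimulationConfig(seed=9)
        baseline = control_baseline(surface_pair, parcellation, cfg)
        sd = cfg.control_noise_sd * baseline
        lesion = parcellation.vertices_of(5)
        rng = np.random.default_rng(9)
        deviations = []
        for _ in range(300):
            values, _ = simulate_patient(
                surface_pair, parcellation, [5], -3.0, cfg, rng=rng
            )
            deviations.append(np.mean((values[lesion] - baseline[lesion]) / sd[lesion]))
        assert abs(np.mean(deviations) / -3.0 - 1.0) < 0.05

    def test_zero_effect_is_a_control_draw(self, surface_pair, parcellation, sim_config):
        rng = np.random.default_rng(3)
        values, _ = simulate_patient(surface_pair, parcellation, [1], 0.0, sim_config, rng=rng)
        from zmapsoz.synthetic import control_baseline

        baseline = control_baseline(surface_pair, parcellation, sim_config)
        z = (values - baseline) / (sim_config.control_noise_sd * baseline)
        assert abs(z.mean()) < 0.1 and abs(z.std() - 1.0) < 0.1


class TestVolumeScene:
    def test_cerebellum_uniform_reference_uptake(self, scene, sim_config):
        mask = scene.cerebellum_mask.data.astype(bool)
        assert np.all(scene.true_activity.data[mask] == sim_config.reference_uptake)

    def test_identity_alignment_ncc_above_gate(self, scene):
        smoothed = gaussian_smooth_volume(scene.anatomical, sigma_mm=2.0)
        assert ncc(smoothed, scene.pet) > 0.85

    def test_zero_psf_identity_alignment_pet_equals_activity(self, sim_config, surface_pair, parcellation):
        cfg = SimulationConfig(seed=0, psf_fwhm_mm=0.0)
        s = simulate_volume_scene(cfg, pair=surface_pair, parcellation=parcellation)
        assert np.array_equal(s.pet.data, s.true_activity.data)

    def test_deterministic(self, sim_config, surface_pair, parcellation):
        a = simulate_volume_scene(sim_config, pair=surface_pair, parcellation=parcellation)
        b = simulate_volume_scene(sim_config, pair=surface_pair, parcellation=parcellation)
        assert np.array_equal(a.anatomical.data, b.anatomical.data)
        assert np.array_equal(a.pet.data, b.pet.data)
        assert np.array_equal(a.labels.data, b.labels.data)

    def test_misalignment_stored_as_aligning_transform(self, sim_config, surface_pair, parcellation):
        t = AffineTransform(translation=[4.0, -3.0, 2.0])
        s = simulate_volume_scene(
            sim_config, pair=surface_pair, parcellation=parcellation, true_affine=t
        )
        from zmapsoz.preproc import resample_affine

        realigned = resample_affine(s.pet, t)
        aligned = simulate_volume_scene(
            sim_config, pair=surface_pair, parcellation=parcellation
        ).pet
        # double trilinear interpolation smooths slightly, so compare by
        # near-perfect correlation over the head rather than exact values
        interior = aligned.data > 0.5
        a = realigned.data[interior]
        b = aligned.data[interior]
        r = np.corrcoef(a, b)[0, 1]
        assert r > 0.995
        assert np.median(np.abs(a - b)) < 0.05


class TestContacts:
    def test_pitch_is_length_plus_gap(self, scene):
        table, _ = simulate_contacts(scene, 2, 8, {1}, seed=0)
        for _, grp in table.df.groupby("electrode"):
            centers = grp[["x", "y", "z"]].to_numpy()
            gaps = np.linalg.norm(np.diff(centers, axis=0), axis=1)
            assert np.allclose(gaps, CONTACT_PITCH_MM)
            # edge-to-edge spacing between 2 mm contacts is 1.5 mm
            assert np.allclose(gaps - 2.0, 1.5)

    def test_interior_contact_ground_truth_is_target_region(self, scene):
        table, truth = simulate_contacts(scene, 1, 5, {4}, seed=0)
        first = table.df.iloc[0]
        assert truth.contact_region_assignments[first["contact_id"]] == 4
        assert bool(first["soz_flag"])

    def test_contacts_per_electrode_bounds(self, scene):
        with pytest.raises(ValueError):
            simulate_contacts(scene, 1, 4, {1}, seed=0)
        with pytest.raises(ValueError):
            simulate_contacts(scene, 1, 19, {1}, seed=0)

    def test_deterministic(self, scene):
        a, _ = simulate_contacts(scene, 3, 6, {2}, seed=11)
        b, _ = simulate_contacts(scene, 3, 6, {2}, seed=11)
        assert a.df.equals(b.df)
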