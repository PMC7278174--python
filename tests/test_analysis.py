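"""Analysis-suite contracts: energy decomposition closure, landscapes,
RMSD/RMSF, pocket volumetry and occupancy hotspot maps."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from sumdcg.analysis import (
    OccupancyGrid,
    distance_profile,
    hotspots,
    interaction_energy_landscape,
    per_residue_interaction_energy,
    pocket_volume,
    rmsd_series,
    rmsf,
    water_occupancy_map,
)
from sumdcg.engine import coulomb_energy, lj_energy
from sumdcg.supervision import centroid_distance
from sumdcg.toy_systems import BeadSpec, ScenarioConfig, System, build_funnel_system

CUTOFF = 9.0


def pair_system(r=3.0, q1=0.5, q2=-1.0):
    """One 1-bead receptor residue and a 1-bead ligand at distance r."""
    beads = [
        BeadSpec(0, 0, "RES", "receptor", 10.0, q1, 2.0, 0.3),
        BeadSpec(1, 1, "LIG", "ligand", 10.0, q2, 2.5, 0.2),
    ]
    coords = np.array([[0.0, 0, 0], [r, 0, 0]])
    return System(beads, coords, site_selection=frozenset([0]),
                  ligand_selection=frozenset([1]))


def multi_residue_system(n_res=10, seed=0):
    rng = np.random.default_rng(seed)
    beads = []
    coords = []
    bid = 0
    for r in range(n_res):
        for _ in range(2):  # two beads per receptor residue
            beads.append(BeadSpec(bid, r, f"R{r}", "receptor", 20.0,
                                  float(rng.uniform(-0.5, 0.5)),
                                  float(rng.uniform(1.5, 2.5)),
                                  float(rng.uniform(0.05, 0.4))))
            coords.append(rng.uniform(-6, 6, 3))
            bid += 1
    for _ in range(3):
        beads.append(BeadSpec(bid, n_res, "LIG", "ligand", 30.0,
                              float(rng.uniform(-0.5, 0.5)), 2.0, 0.25))
        coords.append(rng.uniform(-2, 2, 3))
        bid += 1
    return System(beads, np.array(coords), site_selection=frozenset([0]),
                  ligand_selection=frozenset([n_res]))


class TestDistanceProfile:
    def test_ligand_at_site_centroid_gives_zeros(self):
        sys_ = pair_system(r=0.5)
        frames = np.repeat(sys_.coords[None], 3, axis=0)
        frames[:, 1] = frames[:, 0]  # ligand on top of the site bead
        prof = distance_profile(frames, sys_)
        assert np.allclose(prof["distance_A"], 0.0)

    def test_rigid_translation_changes_distance_exactly(self):
        sys_ = pair_system(r=3.0)
        f0 = sys_.coords.copy()
        f1 = f0.copy()
        f1[1, 0] += 1.0
        prof = distance_profile(np.stack([f0, f1]), sys_)
        assert prof["distance_A"].iloc[1] - prof["distance_A"].iloc[0] == pytest.approx(1.0)

    def test_matches_per_frame_centroid_recomputation(self, funnel_system):
        rng = np.random.default_rng(3)
        frames = funnel_system.coords[None] + rng.normal(0, 0.5, (5, funnel_system.n_beads, 3))
        prof = distance_profile(frames, funnel_system)
        expected = [centroid_distance(funnel_system, f) for f in frames]
        assert np.allclose(prof["distance_A"], expected)

    def test_empty_trajectory_rejected(self, funnel_system):
        with pytest.raises(ValueError):
            distance_profile(np.empty((0, funnel_system.n_beads, 3)), funnel_system)


class TestPerResidueEnergy:
    def test_single_pair_closed_form(self):
        r, q1, q2 = 3.0, 0.5, -1.0
        sys_ = pair_system(r, q1, q2)
        table = per_residue_interaction_energy(sys_.coords[None], sys_, CUTOFF)
        sig = 0.5 * (2.0 + 2.5)
        eps = np.sqrt(0.3 * 0.2)
        assert table.e_vdw[0, 0] == pytest.approx(lj_energy(r, sig, eps, CUTOFF))
        assert table.e_elec[0, 0] == pytest.approx(coulomb_energy(r, q1, q2, CUTOFF))

    def test_residue_beyond_cutoff_contributes_zero(self):
        sys_ = pair_system(r=20.0)
        table = per_residue_interaction_energy(sys_.coords[None], sys_, CUTOFF)
        assert table.e_vdw[0, 0] == 0.0
        assert table.e_elec[0, 0] == 0.0

    def test_decomposition_closure_against_flat_double_loop(self):
        """Residue sums reproduce an independent brute-force pair loop."""
        sys_ = multi_residue_system()
        rng = np.random.default_rng(1)
        frames = sys_.coords[None] + rng.normal(0, 0.3, (4, sys_.n_beads, 3))
        table = per_residue_interaction_energy(frames, sys_, CUTOFF)
        lig = sys_.ligand_bead_indices
        rec = sys_.receptor_bead_indices
        for f in range(4):
            total = 0.0
            for i in lig:
                for j in rec:
                    r = float(np.linalg.norm(frames[f, i] - frames[f, j]))
                    bi, bj = sys_.beads[i], sys_.beads[j]
                    total += lj_energy(r, 0.5 * (bi.lj_sigma + bj.lj_sigma),
                                       np.sqrt(bi.lj_epsilon * bj.lj_epsilon), CUTOFF)
                    total += coulomb_energy(r, bi.charge, bj.charge, CUTOFF)
            assert table.total_per_frame()[f] == pytest.approx(total, abs=1e-6)


class TestLandscape:
    def test_constant_energy(self):
        d = np.array([0.5, 1.5, 2.5, 1.2])
        bins = interaction_energy_landscape(d, np.full(4, -3.0), 1.0)
        assert all(b.mean_energy == -3.0 and b.sd_energy == 0.0 for b in bins)

    def test_hand_binned_pairs(self):
        d = [0.2, 0.8, 1.1, 1.9, 3.5, 3.6]
        e = [1.0, 3.0, 10.0, 20.0, 7.0, 9.0]
        bins = interaction_energy_landscape(d, e, 1.0)
        by_lo = {b.distance_lo: b for b in bins}
        assert set(by_lo) == {0.0, 1.0, 3.0}
        assert by_lo[0.0].mean_energy == pytest.approx(2.0)
        assert by_lo[1.0].mean_energy == pytest.approx(15.0)
        assert by_lo[3.0].mean_energy == pytest.approx(8.0)
        assert by_lo[0.0].n_frames == 2

    def test_frame_counts_conserved(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 30, 500)
        e = rng.normal(size=500)
        bins = interaction_energy_landscape(d, e, 2.0)
        assert sum(b.n_frames for b in bins) == 500

    def test_single_frame(self):
        bins = interaction_energy_landscape([4.2], [-1.0], 1.0)
        assert len(bins) == 1
        assert bins[0].n_frames == 1

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            interaction_energy_landscape([1.0], [1.0], 0.0)


class TestRmsdRmsf:
    def test_identity_trajectory_gives_zero(self, funnel_system):
        frames = np.repeat(funnel_system.coords[None], 3, axis=0)
        assert np.allclose(rmsd_series(frames, funnel_system.coords), 0.0, atol=1e-10)

    def test_pure_rotation_fits_to_zero(self, funnel_system):
        rot = Rotation.from_euler("z", 90, degrees=True)
        rotated = rot.apply(funnel_system.coords)
        out = rmsd_series(rotated[None], funnel_system.coords, superpose=True)
        assert out[0] == pytest.approx(0.0, abs=1e-8)

    def test_translation_without_superposition(self, funnel_system):
        shifted = funnel_system.coords + np.array([2.0, 0.0, 0.0])
        out = rmsd_series(shifted[None], funnel_system.coords, superpose=False)
        assert out[0] == pytest.approx(2.0)

    def test_selection_size_mismatch_rejected(self, funnel_system):
        with pytest.raises(ValueError):
            rmsd_series(funnel_system.coords[None], funnel_system.coords[:5],
                        selection=np.arange(8))

    def test_rmsf_frozen_beads_are_zero(self):
        frames = np.zeros((4, 3, 3))
        frames[:, 0, 0] = [1, -1, 1, -1]  # only bead 0 moves
        out = rmsf(frames)
        assert out[1] == pytest.approx(0.0, abs=1e-10)
        assert out[2] == pytest.approx(0.0, abs=1e-10)

    def test_two_point_alternation_has_unit_rmsf(self):
        """Bead alternating x=-1/x=+1 (others fixed): two-point variance
        gives exactly 1.0 A in the shared frame."""
        base = np.array([[10.0, 0, 0], [0, 10.0, 0], [0, 0, 10.0], [0.0, 0, 0]])
        frames = np.repeat(base[None], 4, axis=0)
        frames[:, 3, 0] = [-1.0, 1.0, -1.0, 1.0]
        out = rmsf(frames, superpose=False)
        assert out[3] == pytest.approx(1.0)
        assert np.allclose(out[:3], 0.0)

    def test_rmsf_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        frames = rng.normal(0, 0.1, (6, 4, 3))
        frames[:, :, :] += np.array([[0, 0, 0], [5, 0, 0], [0, 5, 0], [0, 0, 5]])
        direct = np.sqrt(((frames - frames.mean(0)) ** 2).sum(-1).mean(0))
        assert np.allclose(rmsf(frames, superpose=False), direct, atol=1e-12)
        # rigid-body fitting can only absorb apparent motion in total
        fitted = rmsf(frames, superpose=True)
        assert (fitted**2).sum() <= (direct**2).sum() + 1e-12

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            rmsf(np.zeros((1, 3, 3)))


class TestPocketVolume:
    def test_empty_sphere_matches_analytic_volume(self):
        sys_ = System([BeadSpec(0, 0, "LIG", "ligand", 10, 0, 1.0, 0.1)],
                      np.array([[50.0, 50.0, 50.0]]), box=100.0)
        v = pocket_volume(sys_.coords, sys_, [20.0, 20.0, 20.0], 5.0, spacing=0.5)
        assert v == pytest.approx(4.0 / 3.0 * np.pi * 5.0**3, rel=0.05)

    def test_fully_occluded_site_is_zero(self):
        beads = [BeadSpec(i, i, "SHL", "receptor", 10, 0, 8.0, 0.1) for i in range(1)]
        sys_ = System(beads, np.zeros((1, 3)))
        assert pocket_volume(sys_.coords, sys_, [0.0, 0.0, 0.0], 3.0, spacing=0.5,
                             probe_radius=1.0) == 0.0

    def test_grid_refinement_approaches_analytic_value(self):
        sys_ = System([BeadSpec(0, 0, "LIG", "ligand", 10, 0, 1.0, 0.1)],
                      np.array([[50.0, 50.0, 50.0]]))
        exact = 4.0 / 3.0 * np.pi * 125.0
        coarse = pocket_volume(sys_.coords, sys_, [0.0, 0.0, 0.0], 5.0, spacing=1.0)
        fine = pocket_volume(sys_.coords, sys_, [0.0, 0.0, 0.0], 5.0, spacing=0.5)
        assert abs(fine - exact) <= abs(coarse - exact)

    def test_sphere_outside_box_rejected(self):
        sys_ = System([BeadSpec(0, 0, "LIG", "ligand", 10, 0, 1.0, 0.1)],
                      np.array([[5.0, 5.0, 5.0]]), box=10.0)
        with pytest.raises(ValueError):
            pocket_volume(sys_.coords, sys_, [1.0, 5.0, 5.0], 3.0)


def solvated_line_system(n_solvent=2):
    beads = [BeadSpec(0, 0, "PKT", "receptor", 10, 0, 1.0, 0.0)]
    for i in range(n_solvent):
        beads.append(BeadSpec(1 + i, 1 + i, "SOL", "solvent", 18, 0, 2.8, 0.15))
    coords = np.zeros((1 + n_solvent, 3))
    return System(beads, coords, box=10.0, site_selection=frozenset([0]))


class TestOccupancy:
    def test_static_bead_fills_exactly_one_voxel(self):
        sys_ = solvated_line_system(1)
        frames = np.zeros((100, 2, 3))
        frames[:, 1] = [2.5, 2.5, 2.5]  # centre of voxel (2,2,2) at spacing 1
        grid = water_occupancy_map(frames, sys_, origin=(0, 0, 0), dims=(5, 5, 5),
                                   spacing=1.0)
        assert grid.occupancy[2, 2, 2] == 1.0
        assert grid.occupancy.sum() == 1.0

    def test_fractional_occupancy_counts_frames(self):
        sys_ = solvated_line_system(1)
        frames = np.zeros((100, 2, 3))
        frames[:, 1] = [9.5, 9.5, 9.5]  # parked outside the mapped region
        frames[:10, 1] = [1.5, 1.5, 1.5]
        grid = water_occupancy_map(frames, sys_, origin=(0, 0, 0), dims=(5, 5, 5),
                                   spacing=1.0)
        assert grid.occupancy[1, 1, 1] == pytest.approx(0.10)

    def test_mean_occupancy_equals_global_recount(self):
        """Voxel-mean occupancy == bead-in-voxel observations / (F * V)
        when each in-region bead occupies its own voxel."""
        sys_ = solvated_line_system(3)
        rng = np.random.default_rng(0)
        frames = rng.uniform(0, 10, (50, 4, 3))
        frames[:, 0] = 0.0
        grid = water_occupancy_map(frames, sys_, origin=(0, 0, 0), dims=(10, 10, 10),
                                   spacing=1.0)
        # independent recount: per frame, number of distinct occupied voxels
        occupied = 0
        for f in range(50):
            vox = np.floor(frames[f, 1:]).astype(int)
            ok = np.all((vox >= 0) & (vox < 10), axis=1)
            occupied += len({tuple(v) for v in vox[ok]})
        assert grid.occupancy.mean() == pytest.approx(occupied / (50 * 1000))

    def test_invariant_under_frame_reordering(self):
        sys_ = solvated_line_system(2)
        rng = np.random.default_rng(1)
        frames = rng.uniform(0, 10, (30, 3, 3))
        grid1 = water_occupancy_map(frames, sys_, (0, 0, 0), (10, 10, 10), 1.0)
        grid2 = water_occupancy_map(frames[::-1], sys_, (0, 0, 0), (10, 10, 10), 1.0)
        assert np.array_equal(grid1.occupancy, grid2.occupancy)

    def test_no_solvent_rejected(self, funnel_system):
        with pytest.raises(ValueError, match="solvent"):
            water_occupancy_map(funnel_system.coords[None], funnel_system,
                                (0, 0, 0), (5, 5, 5), 1.0)


class TestHotspots:
    def make_grid(self, values):
        occ = np.zeros((4, 4, 4))
        for idx, v in values.items():
            occ[idx] = v
        return OccupancyGrid(np.zeros(3), 1.0, (4, 4, 4), occ, 100)

    def test_single_hotspot_recovered(self):
        grid = self.make_grid({(1, 2, 3): 0.50})
        hs = hotspots(grid, 0.10)
        assert len(hs) == 1
        assert np.allclose(hs[["x", "y", "z"]].iloc[0], [1.5, 2.5, 3.5])
        assert hs["occupancy"].iloc[0] == 0.50

    def test_threshold_is_strict(self):
        grid = self.make_grid({(0, 0, 0): 0.10})
        assert len(hotspots(grid, 0.10)) == 0

    def test_all_zero_grid_empty_even_at_zero_threshold(self):
        grid = self.make_grid({})
        assert len(hotspots(grid, 0.0)) == 0

    def test_sorted_by_occupancy_then_index(self):
        grid = self.make_grid({(0, 0, 1): 0.3, (0, 0, 2): 0.6, (1, 0, 0): 0.3})
        hs = hotspots(grid, 0.10)
        assert list(hs["occupancy"]) == [0.6, 0.3, 0.3]
        assert list(hs["voxel_index"])[1:] == [1, 16]  # tie broken by index

    def test_bad_threshold_rejected(self):
        grid = self.make_grid({})
        with pytest.raises(ValueError):
            hotspots(grid, 1.0)


class TestHydrationAnalogue:
    """Planted high-residence sites are flagged; a dry variant is not."""

    def test_planted_sites_only(self):
        sys_ = build_funnel_system(ScenarioConfig(n_cryptic_pockets=2, n_solvent=8))
        sol = sys_.indices_by_role("solvent")
        rng = np.random.default_rng(0)
        n_frames, spacing = 100, 1.0
        box = sys_.box
        dims = (int(box),) * 3
        frames = np.repeat(sys_.coords[None], n_frames, axis=0)
        # diffuse background: solvent wanders, at most 5% residence anywhere
        frames[:, sol] = rng.uniform(0, box, (n_frames, sol.size, 3))
        # plant two resident sites at the cryptic sub-pocket mouths (60%)
        site_a = sys_.coords[[i for i, b in enumerate(sys_.beads)
                              if b.residue_name == "CRY"][0]] * 0.99
        site_b = site_a + np.array([0.0, 0.0, -8.0])
        for k, site in enumerate((site_a, site_b)):
            vox_center = (np.floor(site / spacing) + 0.5) * spacing
            frames[: int(0.6 * n_frames), sol[k]] = vox_center
        grid = water_occupancy_map(frames, sys_, (0, 0, 0), dims, spacing)
        hs = hotspots(grid, 0.10)
        assert len(hs) == 2
        got = {tuple(np.floor(r).astype(int))
               for r in hs[["x", "y", "z"]].to_numpy()}
        expected = {tuple(np.floor(site_a).astype(int)),
                    tuple(np.floor(site_b).astype(int))}
        assert got == expected

    def test_dry_variant_has_no_hotspots(self):
        sys_ = build_funnel_system(ScenarioConfig(n_cryptic_pockets=1, n_solvent=4))
        sol = sys_.indices_by_role("solvent")
        rng = np.random.default_rng(1)
        frames = np.repeat(sys_.coords[None], 100, axis=0)
        frames[:, sol] = rng.uniform(0, sys_.box, (100, sol.size, 3))
        grid = water_occupancy_map(frames, sys_, (0, 0, 0), (int(sys_.box),) * 3, 1.0)
        assert len(hotspots(grid, 0.10)) == 0
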