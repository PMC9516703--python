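"""Minimum distances, MDDF, preferential interaction, geometry."""

import itertools

import numpy as np
import pytest

from ilstab import (
    FrameSet,
    TrajectorySpec,
    combine_ion_gammas,
    domain_distances,
    gamma_species,
    generate_trajectory,
    mddf,
    min_distances,
    preferential_interaction,
    rmsf,
    superpose_rmsd,
)
from ilstab.frames_io import load_frameset, save_frameset
from ilstab.errors import PreconditionError


def make_frames(coords_list, species, box=(50.0, 50.0, 50.0), selections=None):
    species = np.array(species, dtype=object)
    return FrameSet(frames=[np.asarray(c, float) for c in coords_list],
                    species=species,
                    molecule_ids=np.arange(species.size),
                    box=np.array(box), selections=selections or {})


class TestMinDistances:
    def test_single_molecule_at_known_distance(self):
        fs = make_frames([[[25.0, 25, 25], [30.0, 25, 25]]], ["solute", "water"])
        d = min_distances(fs, 0, "water")
        assert d[0] == pytest.approx(5.0)

    def test_across_periodic_boundary_matches_image_enumeration(self):
        box = np.array([20.0, 18.0, 16.0])
        rng = np.random.default_rng(0)
        solute = rng.random((4, 3)) * box
        water = rng.random((6, 3)) * box
        coords = np.vstack([solute, water])
        fs = make_frames([coords], ["solute"] * 4 + ["water"] * 6, box=tuple(box))
        d = min_distances(fs, 0, "water")
        # brute force over all 27 periodic images
        shifts = np.array(list(itertools.product([-1, 0, 1], repeat=3))) * box
        for i, w in enumerate(water):
            best = min(np.linalg.norm((w + s) - a)
                       for s in shifts for a in solute)
            assert d[i] == pytest.approx(best, abs=1e-10)

    def test_overlapping_atom_gives_zero(self):
        fs = make_frames([[[25.0, 25, 25], [25.0, 25, 25]]], ["solute", "water"])
        assert min_distances(fs, 0, "water")[0] == 0.0

    def test_missing_species_rejected(self):
        fs = make_frames([[[25.0, 25, 25]]], ["solute"])
        with pytest.raises(PreconditionError):
            min_distances(fs, 0, "water")


class TestMddf:
    def test_uniform_density_near_one(self):
        frames, _ = generate_trajectory(TrajectorySpec(n_frames=10, seed=21))
        res = mddf(frames, "water", bin_width=1.0, r_max=20.0)
        outer = res.bin_edges[:-1] >= 6.0
        observed = res.counts[outer].sum()
        expected = observed / np.nansum(
            res.counts[outer] / np.maximum(res.normalized_density[outer], 1e-12)
        ) if observed else 1.0
        # aggregate density over the far region is close to bulk
        agg = res.counts[outer].sum() / np.nansum(
            res.counts[outer] / np.where(res.normalized_density[outer] > 0,
                                         res.normalized_density[outer], np.nan))
        assert agg == pytest.approx(1.0, abs=0.15)

    def test_enriched_shell_density(self):
        frames, _ = generate_trajectory(
            TrajectorySpec(n_frames=10, seed=22, shell_bias={"cation": 2.0}))
        res = mddf(frames, "cation", bin_width=1.0, r_max=20.0)
        mid = (res.bin_edges[:-1] >= 4.5) & (res.bin_edges[1:] <= 8.5)
        inner = np.nanmean(res.normalized_density[mid])
        assert inner == pytest.approx(2.0, abs=0.5)

    def test_histogram_counts_equal_in_range_molecules(self):
        frames, _ = generate_trajectory(TrajectorySpec(n_frames=3, seed=23))
        res = mddf(frames, "cation", bin_width=0.5, r_max=20.0)
        direct = sum((min_distances(frames, fr, "cation") < 20.0).sum()
                     for fr in range(frames.n_frames))
        assert res.total_count() == direct

    def test_absent_species_flagged_not_crashing(self):
        fs = make_frames([[[25.0, 25, 25], [30.0, 25, 25]]], ["solute", "water"])
        res = mddf(fs, "cation", r_max=20.0)
        assert res.counts.sum() == 0
        assert np.all(np.isnan(res.normalized_density))

    def test_r_max_beyond_half_box_rejected(self):
        frames, _ = generate_trajectory(TrajectorySpec(n_frames=1, seed=1))
        with pytest.raises(PreconditionError):
            mddf(frames, "water", r_max=40.0)


class TestGammaSpecies:
    def test_uniform_system_gamma_near_zero(self):
        frames, _ = generate_trajectory(TrajectorySpec(n_frames=15, seed=31))
        g = gamma_species(frames, "cation")
        assert abs(g.gamma) < 3 * g.se + 1e-9

    def test_exact_agreement_with_direct_counting_oracle(self):
        frames, gt = generate_trajectory(
            TrajectorySpec(n_frames=6, seed=32, shell_bias={"cation": 2.0}))
        g = gamma_species(frames, "cation", cutoff_r=12.0)
        oracle = gt.gamma("cation", 12.0)
        np.testing.assert_allclose(g.per_frame, oracle, atol=1e-10)

    def test_enrichment_and_depletion_signs(self):
        up, _ = generate_trajectory(
            TrajectorySpec(n_frames=10, seed=33, shell_bias={"cation": 2.5}))
        down, _ = generate_trajectory(
            TrajectorySpec(n_frames=10, seed=33, shell_bias={"cation": 0.4}))
        assert gamma_species(up, "cation").gamma > 0
        assert gamma_species(down, "cation").gamma < 0

    def test_monotone_in_enrichment(self):
        gammas = []
        for factor in (0.5, 1.0, 2.0, 4.0):
            frames, _ = generate_trajectory(
                TrajectorySpec(n_frames=10, seed=34, shell_bias={"cation": factor}))
            gammas.append(gamma_species(frames, "cation").gamma)
        assert gammas == sorted(gammas)

    def test_small_cutoff_well_defined(self):
        frames, _ = generate_trajectory(TrajectorySpec(n_frames=3, seed=35))
        g = gamma_species(frames, "cation", cutoff_r=1.0)
        assert np.isfinite(g.gamma)


class TestCombineIonGammas:
    def test_zero_inputs_all_forms(self):
        for form in ("sum", "half_sum", "half_sum_minus_half_z"):
            assert combine_ion_gammas(0.0, 0.0, 0.0, form) == 0.0

    def test_default_form_hand_value(self):
        assert combine_ion_gammas(20.0, 4.0, 22.0) == pytest.approx(1.0)

    def test_symmetric_in_ions(self):
        a = combine_ion_gammas(7.0, -3.0, 10.0)
        b = combine_ion_gammas(-3.0, 7.0, 10.0)
        assert a == b

    def test_full_pipeline_runs(self):
        frames, _ = generate_trajectory(
            TrajectorySpec(n_frames=5, seed=36, shell_bias={"cation": 2.0}))
        pi = preferential_interaction(frames, z2=22.0)
        assert pi.gamma_23 == pytest.approx(
            (pi.gamma_plus + pi.gamma_minus) / 2 - 11.0)


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestSuperposition:
    def _frameset(self, frames):
        n = frames[0].shape[0]
        return FrameSet(frames=frames, species=np.array(["solute"] * n, dtype=object),
                        molecule_ids=np.zeros(n, dtype=int),
                        box=np.array([500.0, 500.0, 500.0]))

    def test_identical_frame_zero_rmsd(self):
        rng = np.random.default_rng(1)
        c = rng.random((30, 3)) * 10
        assert superpose_rmsd(self._frameset([c, c.copy()]))[1] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(2)
        c = rng.random((40, 3)) * 10
        moved = c @ _random_rotation(rng).T + np.array([5.0, -3.0, 2.0])
        rmsds = superpose_rmsd(self._frameset([c, moved]))
        assert rmsds[1] < 1e-8

    def test_single_displaced_atom_matches_quaternion_search(self):
        rng = np.random.default_rng(3)
        c = rng.random((100, 3)) * 20
        d = c.copy()
        d[0] += np.array([1.0, 0.0, 0.0])
        rmsd = superpose_rmsd(self._frameset([c, d]))[1]
        # brute-force: best RMSD over many random rigid placements can only
        # be worse than or equal to the optimal superposition
        best = np.inf
        for _ in range(300):
            rot = _random_rotation(rng)
            moved = d @ rot.T
            offset = c.mean(axis=0) - moved.mean(axis=0)
            best = min(best, float(np.sqrt(((moved + offset - c) ** 2)
                                           .sum(axis=1).mean())))
        assert rmsd <= best + 1e-12
        assert rmsd == pytest.approx(0.1, abs=0.02)

    def test_rmsf_zero_for_rigid_motion(self):
        rng = np.random.default_rng(4)
        c = rng.random((25, 3)) * 10
        frames = [c] + [c @ _random_rotation(rng).T + rng.normal(size=3)
                        for _ in range(4)]
        assert np.max(rmsf(self._frameset(frames))) < 1e-8

    def test_small_selection_rejected(self):
        fs = self._frameset([np.zeros((2, 3)), np.ones((2, 3))])
        with pytest.raises(PreconditionError):
            superpose_rmsd(fs)


class TestDomainDistances:
    def _fs(self, triangle, n_frames=1):
        coords = np.asarray(triangle, float)
        sels = {"Fab1": np.array([0]), "Fab2": np.array([1]), "Fc": np.array([2])}
        return FrameSet(frames=[coords] * n_frames,
                        species=np.array(["solute"] * 3, dtype=object),
                        molecule_ids=np.arange(3), box=np.array([100.0] * 3),
                        selections=sels)

    def test_equilateral_is_y(self):
        call = domain_distances(self._fs([[0, 0, 0], [10, 0, 0], [5, 8.66, 0]]))
        assert call.label == "Y"

    def test_folded_arm_is_lambda(self):
        call = domain_distances(self._fs([[0, 0, 0], [10, 0, 0], [4, 3, 0]]))
        assert call.label == "lambda"

    def test_half_and_half_is_ambiguous(self):
        y = np.array([[0, 0, 0], [10, 0, 0], [5, 8.66, 0]], float)
        lam = np.array([[0, 0, 0], [10, 0, 0], [4, 3, 0]], float)
        sels = {"Fab1": np.array([0]), "Fab2": np.array([1]), "Fc": np.array([2])}
        fs = FrameSet(frames=[y, lam], species=np.array(["solute"] * 3, dtype=object),
                      molecule_ids=np.arange(3), box=np.array([100.0] * 3),
                      selections=sels)
        assert domain_distances(fs).label == "ambiguous"

    def test_missing_selection_rejected(self):
        fs = self._fs([[0, 0, 0], [10, 0, 0], [5, 8.66, 0]])
        fs.selections.pop("Fc")
        with pytest.raises(PreconditionError):
            domain_distances(fs)


class TestFrameIO:
    def test_xyz_round_trip(self, tmp_path):
        frames, _ = generate_trajectory(
            TrajectorySpec(n_frames=3, seed=8,
                           species_counts={"cation": 5, "anion": 5, "water": 10}))
        path = tmp_path / "traj.xyz"
        save_frameset(frames, path)
        back = load_frameset(path)
        assert back.n_frames == frames.n_frames
        np.testing.assert_array_equal(back.species, frames.species)
        np.testing.assert_array_equal(back.molecule_ids, frames.molecule_ids)
        for a, b in zip(back.frames, frames.frames):
            np.testing.assert_allclose(a, b, atol=1e-3)  # XYZ text precision
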