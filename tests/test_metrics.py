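"""Trajectory metrics: superposition, RMSD/RMSF, secondary structure, angles,
displacement maps, and autocorrelation-aware uncertainty estimates."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from haplodyn.core import RegionSelection, SelectionError, TopologyError, Trajectory
from haplodyn import metrics as M
from haplodyn.synthetic import SyntheticSpec, gen_ar1, gen_helix_coil_trajectory
from tests.conftest import backbone_trajectory


def static_copy(traj, n_frames=5):
    return dataclasses.replace(
        traj, coordinates=np.repeat(traj.coordinates[:1], n_frames, axis=0))


class TestSuperpose:
    def test_identical_frames_zero_rmsd(self, ideal_helix):
        ref = ideal_helix.coordinates[0]
        _, rmsd = M.superpose(ref.copy(), ref)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_removed(self, ideal_helix, seed):
        rng = np.random.default_rng(seed)
        ref = ideal_helix.coordinates[0]
        rot = Rotation.random(rng=rng)
        moved = rot.apply(ref) + rng.uniform(-10, 10, 3)
        _, rmsd = M.superpose(moved, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_single_atom_offset_closed_form(self, ideal_helix):
        # without refitting, displacing one of N atoms by 1 A gives 1/sqrt(N)
        ref = ideal_helix.coordinates[0]
        mask = ideal_helix.atom_mask(RegionSelection(atom_names=("CA",)))
        moved = ref.copy()
        moved[np.flatnonzero(mask)[4]] += [1.0, 0, 0]
        rmsd = M._masked_rmsd(moved, ref, mask)
        assert rmsd == pytest.approx(1 / np.sqrt(mask.sum()))

    def test_atom_count_mismatch_raises(self, ideal_helix):
        ref = ideal_helix.coordinates[0]
        with pytest.raises(SelectionError):
            M.superpose(ref[:-1], ref)


class TestRmsdSeries:
    def test_static_trajectory_all_zero(self, ideal_helix):
        traj = static_copy(ideal_helix)
        _, v = M.rmsd_series(traj, traj.coordinates[0],
                             RegionSelection(atom_names=("CA",)), stride_ps=200)
        assert np.allclose(v, 0.0, atol=1e-9)

    def test_known_uniform_displacement(self, ideal_helix):
        traj = static_copy(ideal_helix, n_frames=4)
        sel = RegionSelection.residues(3, 6)
        align = RegionSelection.residues(8, 12)
        mask = traj.atom_mask(sel)
        coords = traj.coordinates.copy()
        for f, d in enumerate([0.0, 0.5, 1.0, 2.0]):
            coords[f, mask] += [0, 0, d]
        traj = dataclasses.replace(traj, coordinates=coords)
        _, v = M.rmsd_series(traj, traj.coordinates[0], sel,
                             align_selection=align, stride_ps=200)
        assert v == pytest.approx([0.0, 0.5, 1.0, 2.0], abs=1e-9)

    def test_stride_below_interval_rejected(self, ideal_helix):
        with pytest.raises(ValueError):
            M.rmsd_series(static_copy(ideal_helix), ideal_helix.coordinates[0],
                          RegionSelection(atom_names=("CA",)), stride_ps=50)


class TestRmsf:
    def test_static_trajectory_zero(self, ideal_helix):
        _, v = M.rmsf(static_copy(ideal_helix), RegionSelection(atom_names=("CA",)))
        assert np.allclose(v, 0.0, atol=1e-9)

    def test_single_frame_rejected(self, ideal_helix):
        with pytest.raises(ValueError):
            M.rmsf(static_copy(ideal_helix, 1), RegionSelection(atom_names=("CA",)))

    def test_isotropic_jitter_converges_to_sigma_sqrt3(self, ideal_helix):
        sigma = 0.3
        n = 4000
        traj = static_copy(ideal_helix, n)
        rng = np.random.default_rng(0)
        coords = traj.coordinates.copy()
        target = ideal_helix.atom_index(6, "CA")
        coords[:, target] += rng.normal(scale=sigma, size=(n, 3))
        traj = dataclasses.replace(traj, coordinates=coords)
        # align on far residues so the jittered atom does not bias the fit
        resids, v = M.rmsf(traj, RegionSelection(atom_names=("CA",)),
                           align_selection=RegionSelection.residues(9, 12),
                           stride_ps=200)
        est = v[resids == 6][0]
        expect = sigma * np.sqrt(3)
        se = expect / np.sqrt(2 * n)   # delta-method scale for the check
        assert abs(est - expect) < 5 * se

    def test_identical_replicas_zero_sem(self, ideal_helix):
        traj = static_copy(ideal_helix)
        _, mean, sem = M.rmsf_replicas([traj, traj, traj],
                                       RegionSelection(atom_names=("CA",)))
        assert np.allclose(sem, 0.0)


class TestAssignSS:
    def test_ideal_helix_interior_all_helix(self, ideal_helix):
        labels = M.assign_ss(ideal_helix)[0]
        assert all(l == "H" for l in labels[1:-1])
        assert labels[0] == "-" and labels[-1] == "-"

    def test_extended_chain_all_loop(self):
        ext = backbone_trajectory([-139.0] * 10, [135.0] * 10)
        assert all(l == "-" for l in M.assign_ss(ext)[0])

    def test_hairpin_strands_and_turn(self, hairpin):
        labels = "".join(M.assign_ss(hairpin)[0])
        assert labels == "-EEEEE--EEEEE-"

    def test_invariant_under_rigid_motion(self, ideal_helix):
        rng = np.random.default_rng(3)
        rot = Rotation.random(rng=rng)
        moved = dataclasses.replace(
            ideal_helix,
            coordinates=(rot.apply(ideal_helix.coordinates[0]) + [3.0, -7.0, 11.0])[None])
        assert (M.assign_ss(moved) == M.assign_ss(ideal_helix)).all()

    def test_missing_backbone_atom_raises(self, ideal_helix):
        broken = dataclasses.replace(ideal_helix)
        keep = ~((broken.resids == 5) & (broken.atom_names == "O"))
        broken = Trajectory(broken.coordinates[:, keep], broken.resids[keep],
                            broken.resnames[keep], broken.atom_names[keep],
                            broken.elements[keep])
        with pytest.raises(TopologyError):
            M.assign_ss(broken)


class TestOrderedFraction:
    def test_all_helix_is_one(self):
        labels = np.full((5, 8), "H", dtype=object)
        frac, series = M.ordered_fraction(labels)
        assert frac == 1.0 and np.all(series == 1.0)

    def test_empty_region_rejected(self):
        with pytest.raises(SelectionError):
            M.ordered_fraction(np.full((2, 4), "H", dtype=object),
                               np.zeros(4, dtype=bool))

    def test_recovers_planted_helix_probability(self, helix_coil_60):
        spec, traj = helix_coil_60
        labels = M.assign_ss(traj)
        mask = np.zeros(spec.n_residues, dtype=bool)
        mask[1:-1] = True
        frac, _ = M.ordered_fraction(labels, mask)
        se = np.sqrt(0.6 * 0.4 / spec.n_frames)
        assert abs(frac - spec.helix_probability) < 3 * se


class TestSSChangeFraction:
    def test_identical_labels_zero(self):
        labels = np.full((3, 6), "H", dtype=object)
        assert np.all(M.ss_change_fraction(labels, labels[0]) == 0.0)

    def test_half_flipped(self):
        ref = np.array(["H"] * 4 + ["-"] * 4, dtype=object)
        frames = np.tile(ref, (3, 1))
        frames[:, :2] = "-"
        frames[:, 4:6] = "H"
        assert np.all(M.ss_change_fraction(frames, ref) == 0.5)

    def test_complete_change(self):
        ref = np.full(5, "H", dtype=object)
        frames = np.full((2, 5), "-", dtype=object)
        assert np.all(M.ss_change_fraction(frames, ref) == 1.0)

    def test_residue_set_mismatch(self):
        with pytest.raises(SelectionError):
            M.ss_change_fraction(np.full((2, 5), "H", dtype=object),
                                 np.full(4, "H", dtype=object))


class TestKinkAngle:
    def test_orthogonal_and_collinear_points(self, ideal_helix):
        traj = static_copy(ideal_helix, 1)
        coords = traj.coordinates.copy()
        ca = [traj.atom_index(r, "CA") for r in (3, 7, 11)]
        coords[0, ca[0]] = [1, 0, 0]
        coords[0, ca[1]] = [0, 0, 0]
        coords[0, ca[2]] = [0, 1, 0]
        traj = dataclasses.replace(traj, coordinates=coords)
        assert M.kink_angle(traj, (3, 7, 11))[0] == pytest.approx(90.0)
        coords[0, ca[2]] = [-2, 0, 0]
        traj = dataclasses.replace(traj, coordinates=coords)
        assert M.kink_angle(traj, (3, 7, 11))[0] == pytest.approx(180.0)

    def test_missing_atom_raises(self, ideal_helix):
        with pytest.raises(TopologyError):
            M.kink_angle(ideal_helix, (3, 7, 11), atom_name="CB")


class TestDisplacementMap:
    def test_static_at_reference_is_zero(self, ideal_helix):
        traj = static_copy(ideal_helix)
        _, D = M.displacement_map(traj, traj.coordinates[0])
        assert np.allclose(D, 0.0, atol=1e-9)

    def test_symmetric_zero_diagonal(self, helix_coil_60):
        _, traj = helix_coil_60
        sub = traj.slice_frames(slice(0, 50))
        _, D = M.displacement_map(sub, sub.coordinates[0])
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0.0)

    def test_rigidly_displaced_residue_row(self, ideal_helix):
        traj = static_copy(ideal_helix, 3)
        coords = traj.coordinates.copy()
        idx = traj.atom_index(12, "CA")
        # move the terminal residue 2 A further along the chain axis
        axis = coords[0, idx] - coords[0, traj.atom_index(1, "CA")]
        axis /= np.linalg.norm(axis)
        coords[:, traj.resids == 12] += 2.0 * axis
        moved = dataclasses.replace(traj, coordinates=coords)
        resids, D = M.displacement_map(moved, traj.coordinates[0])
        row = D[resids == 12][0]
        # moving away along the separation axis adds close to +2 A for
        # residues far down the chain
        assert row[0] == pytest.approx(2.0, abs=0.25)
        assert np.all(row[:-1] > 0)


class TestAutocorrelation:
    def test_white_noise_tau_one(self):
        x = gen_ar1(50000, 0.0, seed=2)
        assert M.autocorrelation_time(x) == 1

    @pytest.mark.parametrize("rho,expect,tol", [(0.9, 10, 1),
                                                (np.exp(-1 / 25), 25, 2)])
    def test_ar1_closed_form(self, rho, expect, tol):
        x = gen_ar1(100_000, rho, seed=4)
        assert abs(M.autocorrelation_time(x) - expect) <= tol

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            M.autocorrelation_time(np.ones(100))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            M.autocorrelation_time(np.arange(5))


class TestMovingBlockBootstrap:
    def test_constant_series_zero_sem(self):
        st = M.moving_block_bootstrap_sem(np.ones(100), n_boot=50, seed=0)
        assert st.sem == 0.0

    def test_iid_matches_sigma_over_sqrt_n(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=10_000)
        st = M.moving_block_bootstrap_sem(x, block_length=1, n_boot=2000, seed=1)
        assert abs(st.sem - 0.01) / 0.01 < 0.10

    def test_ar1_block_tau_matches_block_level_oracle(self):
        # with block = ceil(tau), the MBB converges to the *block-l* variance
        # sigma2_l = 1 + (2/l) sum_{k<l} (l-k) rho^k, not the long-run value
        rho, n = 0.9, 100_000
        x = gen_ar1(n, rho, seed=5)
        st = M.moving_block_bootstrap_sem(x, n_boot=400, seed=2)
        l = st.block_length
        sig2_l = 1 + (2 / l) * sum((l - k) * rho ** k for k in range(1, l))
        expect = np.sqrt(sig2_l / n)
        assert abs(st.sem - expect) / expect < 0.25

    def test_long_blocks_recover_long_run_variance(self):
        rho, n = 0.9, 100_000
        x = gen_ar1(n, rho, seed=5)
        tau = M.autocorrelation_time(x)
        st = M.moving_block_bootstrap_sem(x, block_length=5 * tau, n_boot=400, seed=3)
        expect = np.sqrt((1 + rho) / (1 - rho) / n)
        assert abs(st.sem - expect) / expect < 0.25

    def test_block_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            M.moving_block_bootstrap_sem(np.arange(10.0), block_length=11)


class TestReplicaMeanSem:
    def test_equal_means(self):
        st = M.replica_mean_sem([1.0, 1.0, 1.0])
        assert st.mean == 1.0 and st.sem == 0.0

    def test_hand_computed_sem(self):
        st = M.replica_mean_sem([0.0, 1.0, 2.0])
        assert st.mean == 1.0
        assert st.sem == pytest.approx(np.std([0, 1, 2], ddof=1) / np.sqrt(3))

    def test_single_replica_flagged(self):
        st = M.replica_mean_sem([1.5])
        assert st.sem is None and st.n_replicas == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            M.replica_mean_sem([])


class TestEquilibrationCut:
    def test_cut_removes_prefix(self, helix_coil_60):
        _, traj = helix_coil_60
        cut = traj.discard_initial_ns(10.0)   # 10 ns / 200 ps = 50 frames
        assert cut.n_frames == traj.n_frames - 50
        assert np.array_equal(cut.coordinates[0], traj.coordinates[50])

    def test_cut_longer_than_trajectory_rejected(self, ideal_helix):
        with pytest.raises(ValueError):
            ideal_helix.discard_initial_ns(1000.0)
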