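import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import lipswitch as lw
from lipswitch.geometry import SegmentSpec, masses_from_atom_names, segment_axis

from conftest import make_atoms


def membrane_frame(n_z, protein_coords=None, protein_res=None):
    """Membrane 'N' atoms at given z values, optionally plus protein atoms."""
    nz = np.asarray(n_z, dtype=float)
    coords = np.column_stack([np.zeros_like(nz), np.zeros_like(nz), nz])
    atoms = make_atoms(
        coords,
        atom_names=["N"] * len(nz),
        res_ids=np.arange(1, len(nz) + 1),
        chain="M",
        leaflet=[1] * len(nz),
    )
    if protein_coords is not None:
        prot = make_atoms(np.asarray(protein_coords, float), res_ids=protein_res)
        atoms = prot + atoms
    return atoms


class TestMembranePlane:
    def test_mean_of_upper_leaflet_nitrogens(self):
        assert lw.membrane_plane_z(membrane_frame([20, 20, 20])) == 20.0
        assert lw.membrane_plane_z(membrane_frame([19, 20, 21])) == pytest.approx(20.0)

    def test_matches_direct_summation_on_jittered_atoms(self):
        rng = np.random.default_rng(0)
        z = rng.normal(19.0, 1.0, 500)
        frame = membrane_frame(z)
        stored = frame.coord[:, 2].astype(np.float64)
        assert lw.membrane_plane_z(frame) == pytest.approx(
            stored.sum() / 500, abs=1e-12
        )

    def test_errors_without_qualifying_atoms(self):
        frame = make_atoms([[0, 0, 0]], atom_names=["CA"])
        with pytest.raises(ValueError):
            lw.membrane_plane_z(frame)


class TestCom:
    def test_single_atom_and_equal_masses(self):
        np.testing.assert_allclose(lw.com([[1.0, 2.0, 3.0]]), [1, 2, 3])
        assert lw.com([[0, 0, 0], [0, 0, 10]])[2] == 5.0

    def test_hand_weighted_mean(self):
        assert lw.com([[0, 0, 0], [0, 0, 4]], masses=[1, 3])[2] == pytest.approx(3.0)

    def test_empty_or_bad_masses_rejected(self):
        with pytest.raises(ValueError):
            lw.com(np.empty((0, 3)))
        with pytest.raises(ValueError):
            lw.com([[0, 0, 0]], masses=[0.0])


class TestHeights:
    def test_signed_height_arithmetic(self):
        # protein COM at z=36.1 over a plane at z=20 -> 16.1 A
        frame = membrane_frame([20.0] * 3, protein_coords=[[0, 0, 36.1]])
        assert lw.protein_height(frame) == pytest.approx(16.1)
        below = membrane_frame([20.0] * 3, protein_coords=[[0, 0, 20.0]])
        assert lw.protein_height(below) == pytest.approx(0.0)

    def test_invariant_under_whole_system_z_shift(self):
        frame = membrane_frame([20.0, 21.0], protein_coords=[[0, 0, 30], [0, 0, 40]])
        h0 = lw.protein_height(frame)
        frame.coord[:, 2] += 7.0
        assert lw.protein_height(frame) == pytest.approx(h0, abs=1e-12)

    def test_entry_height_composes_com_and_plane(self):
        coords = [[0, 0, 22.0], [0, 0, 25.0], [0, 0, 26.13]]
        frame = membrane_frame([20.0] * 4, protein_coords=coords,
                               protein_res=[129, 185, 190])
        spec = SegmentSpec(entry_residues=(129, 185, 190))
        stored = frame.coord[:3, 2].astype(np.float64)
        expected = stored.mean() - 20.0
        assert lw.entry_height(frame, spec) == pytest.approx(expected, abs=1e-12)
        assert lw.entry_height(frame, spec) == pytest.approx(4.376666, abs=1e-4)

    def test_entry_height_names_missing_residue(self):
        frame = membrane_frame([20.0], protein_coords=[[0, 0, 0]], protein_res=[129])
        with pytest.raises(ValueError, match="185"):
            lw.entry_height(frame, SegmentSpec(entry_residues=(129, 185, 190)))


class TestSegmentAngle:
    def _frame_with_axis(self, direction):
        direction = np.asarray(direction, float)
        direction /= np.linalg.norm(direction)
        pts = np.outer(np.arange(11, dtype=float), direction)
        prot = make_atoms(pts, res_ids=np.arange(346, 357))
        memb = membrane_frame([0.0] * 3)
        return prot + memb

    def test_axis_along_z_is_perpendicular_to_plane(self):
        assert lw.segment_angle(self._frame_with_axis([0, 0, 1])) == pytest.approx(90.0)

    def test_axis_in_plane_is_zero(self):
        assert lw.segment_angle(self._frame_with_axis([1, 0, 0])) == pytest.approx(0.0, abs=1e-9)

    def test_45_degrees_closed_form(self):
        assert lw.segment_angle(self._frame_with_axis([1, 0, 1])) == pytest.approx(45.0)

    def test_normal_reference_is_complementary(self):
        frame = self._frame_with_axis([1, 0, 2])
        assert lw.segment_angle(frame, angle_ref="plane") + lw.segment_angle(
            frame, angle_ref="normal"
        ) == pytest.approx(90.0)

    def test_endpoint_axis_agrees_with_pca_on_straight_segment(self):
        frame = self._frame_with_axis([1, 1, 1])
        a = segment_axis(frame, method="pca")
        b = segment_axis(frame, method="endpoints")
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_degenerate_segment_rejected(self):
        prot = make_atoms(np.zeros((11, 3)), res_ids=np.arange(346, 357))
        frame = prot + membrane_frame([0.0])
        with pytest.raises(ValueError, match="degenerate"):
            lw.segment_angle(frame)


class TestContactFractions:
    def _traj(self, res_z_by_frame):
        """Frames with one residue per z entry; plane at 0 from 4 'N' atoms."""
        import biotite.structure as struc

        frames = []
        for zs in res_z_by_frame:
            prot = make_atoms(
                [[0.0, 0.0, z] for z in zs], res_ids=np.arange(1, len(zs) + 1)
            )
            memb = membrane_frame([0.0] * 4)
            frames.append(prot + memb)
        return lw.Trajectory(struc.stack(frames), frame_interval_ps=100.0)

    def test_always_within_threshold_gives_100(self):
        traj = self._traj([[3.0]] * 10)
        assert lw.contact_fractions(traj).loc[1, "f_percent"] == 100.0

    def test_exactly_at_threshold_is_not_a_contact(self):
        traj = self._traj([[5.0]] * 10)
        assert lw.contact_fractions(traj, threshold=5.0).loc[1, "f_percent"] == 0.0

    def test_counting_oracle_half_below_plane(self):
        zs = [[-1.0]] * 25 + [[10.0]] * 25
        traj = self._traj(zs)
        assert lw.contact_fractions(traj).loc[1, "f_percent"] == pytest.approx(50.0)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        zs = rng.uniform(-2, 12, (30, 4)).tolist()
        traj = self._traj(zs)
        previous = None
        for thr in (1.0, 3.0, 5.0, 8.0, 15.0):
            f = lw.contact_fractions(traj, threshold=thr)["f_percent"].to_numpy()
            if previous is not None:
                assert (f >= previous - 1e-12).all()
            previous = f

    def test_empty_window_rejected(self):
        traj = self._traj([[0.0]] * 3)
        with pytest.raises(ValueError):
            lw.contact_fractions(traj, window=(2, 2))


class TestSampleSeries:
    def test_one_sample_per_frame_and_stride_counts(self, noiseless_traj):
        traj, _, _ = noiseless_traj
        assert len(lw.sample_series(traj)) == traj.n_frames
        # 2 ns at 100 ps -> 20 frames; 200 ps stride -> 10 samples
        assert len(lw.sample_series(traj, every_ps=200.0)) == traj.n_frames // 2

    def test_non_multiple_stride_rejected(self, noiseless_traj):
        traj, _, _ = noiseless_traj
        with pytest.raises(ValueError):
            lw.sample_series(traj, every_ps=150.0)


class TestRmsd:
    def test_identical_frames_zero(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(20, 3))
        assert lw.rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(20, 3))
        b = a + np.array([3.0, 4.0, 0.0])
        assert lw.rmsd(a, b, superpose=False) == pytest.approx(5.0)
        assert lw.rmsd(a, b, superpose=True) == pytest.approx(0.0, abs=1e-9)

    def test_superposed_never_exceeds_unsuperposed(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.normal(size=(15, 3))
            b = a + rng.normal(scale=0.5, size=(15, 3))
            assert lw.rmsd(a, b, True) <= lw.rmsd(a, b, False) + 1e-12

    def test_matches_numerical_rotation_search(self):
        """Kabsch optimum agrees with an independent rotation-space minimizer."""
        rng = np.random.default_rng(8)
        a = rng.normal(size=(20, 3))
        true_rot = Rotation.random(rng=np.random.default_rng(9))
        b = true_rot.apply(a) + rng.normal(scale=0.1, size=(20, 3))
        kab = lw.rmsd(a, b, superpose=True)

        ac, bc = a - a.mean(0), b - b.mean(0)

        def objective(rotvec):
            rot = Rotation.from_rotvec(rotvec)
            return np.sqrt(((rot.apply(ac) - bc) ** 2).sum(axis=1).mean())

        best = min(
            (
                minimize(objective, Rotation.random(rng=np.random.default_rng(s)).as_rotvec(),
                         method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12}).fun
                for s in range(6)
            )
        )
        assert abs(kab - best) <= 1e-3
        assert kab <= best + 1e-9

    def test_mismatched_atom_counts_rejected(self):
        with pytest.raises(ValueError):
            lw.rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


def test_rmsf_zero_for_rigid_motion(noiseless_traj):
    """A rigidly moving protein has (numerically) zero internal fluctuation."""
    traj, _, _ = noiseless_traj
    table = lw.rmsf(traj)
    assert table["rmsf"].max() < 1e-9


def test_mass_lookup_skips_leading_digits():
    masses = masses_from_atom_names(["CA", "N", "1HB", "OXT"])
    assert masses[1] == pytest.approx(14.007)
    assert masses[2] == pytest.approx(1.008)
    assert masses[3] == pytest.approx(15.999)
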