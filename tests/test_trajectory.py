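"""Trajectory analysis: superposition, RMSD/Rg/RMSF, cutoff clustering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from flavodesc.synthetic import gen_trajectory
from flavodesc.trajectory import (
    Trajectory,
    gromos_cluster,
    kabsch_superpose,
    pair_rmsd,
    radius_of_gyration,
    rmsd_series,
    rmsf_per_atom,
    rmsf_per_residue,
)


def _traj(frames, masses=None):
    frames = np.asarray(frames, float)
    n = frames.shape[1]
    return Trajectory(
        atom_names=[f"A{i}" for i in range(n)],
        masses=np.ones(n) if masses is None else masses,
        residue_index=np.arange(n),
        frames=frames,
    )


def _random_rigid(rng):
    R = Rotation.random(random_state=np.random.RandomState(int(rng.integers(1 << 30))))
    return R.as_matrix(), rng.normal(size=3)


class TestKabsch:
    def test_identity_on_equal_coordinates(self, rng):
        X = rng.normal(size=(6, 3))
        R, t, rmsd = kabsch_superpose(X, X)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert R == pytest.approx(np.eye(3), abs=1e-10)

    def test_rigid_motion_recovered(self, rng):
        X = rng.normal(size=(10, 3))
        Q, shift = _random_rigid(rng)
        R, t, rmsd = kabsch_superpose(X @ Q.T + shift, X)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_matches_scipy_and_quaternion_sampling(self, rng):
        """Optimal RMSD agrees with scipy's Kabsch and is a lower bound for
        a brute-force search over random rotations."""
        X = rng.normal(size=(10, 3))
        Y = rng.normal(size=(10, 3))
        _, _, rmsd = kabsch_superpose(X, Y)
        assert rmsd <= pair_rmsd(X, Y, superpose=False) + 1e-12
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        _, rssd = Rotation.align_vectors(Yc, Xc)
        assert rmsd == pytest.approx(rssd / np.sqrt(len(X)), rel=1e-6)
        samples = Rotation.random(4000, random_state=7).as_matrix()
        sampled = min(
            np.sqrt(np.mean(np.sum((Xc @ S.T - Yc) ** 2, axis=1))) for S in samples
        )
        assert rmsd <= sampled + 1e-12
        assert rmsd == pytest.approx(sampled, rel=0.05)  # 4000 draws get close

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError, match="3 atoms"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(rng.normal(size=(5, 3)), line)


class TestRmsdSeries:
    def test_static_trajectory_all_zero(self):
        traj, truth = gen_trajectory("static", {"n_frames": 20}, seed=0)
        assert rmsd_series(traj) == pytest.approx(truth["rmsd"], abs=1e-12)

    def test_rigidly_displaced_frame_is_zero(self, rng):
        base = rng.normal(size=(8, 3))
        Q, shift = _random_rigid(rng)
        traj = _traj([base, base @ Q.T + shift])
        assert rmsd_series(traj)[1] == pytest.approx(0.0, abs=1e-10)
        assert rmsd_series(traj, superpose=False)[1] > 0.1

    def test_wobble_closed_form(self):
        traj, truth = gen_trajectory(
            "wobble", {"n_atoms": 10, "n_frames": 48, "amplitude": 0.05}, seed=2
        )
        series = rmsd_series(traj, superpose=False)
        assert np.abs(series - truth["rmsd_raw"]).max() < 1e-9

    def test_reference_and_selection_contracts(self, rng):
        traj = _traj(rng.normal(size=(3, 5, 3)))
        assert rmsd_series(traj, reference_frame=1)[1] == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError, match="out of range"):
            rmsd_series(traj, reference_frame=9)
        with pytest.raises(ValueError, match="empty"):
            rmsd_series(traj, selection=[])


class TestRadiusOfGyration:
    def test_two_unit_masses(self):
        d = 0.8
        frame = [[0, 0, 0], [d, 0, 0]]
        assert radius_of_gyration(frame, [1.0, 1.0]) == pytest.approx(d / 2)

    def test_single_atom_zero(self):
        assert radius_of_gyration([[1.0, 2.0, 3.0]], [5.0]) == 0.0

    def test_cube_lattice_direct_sum_oracle(self):
        s = 0.31
        pts = np.array(
            [[i * s, j * s, k * s] for i in range(5) for j in range(5) for k in range(5)]
        )
        m = np.ones(len(pts))
        com = pts.mean(axis=0)
        expected = np.sqrt(np.sum((pts - com) ** 2) / len(pts))
        assert radius_of_gyration(pts, m) == pytest.approx(expected, rel=1e-14)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(12, 3))
        m = rng.uniform(1, 16, size=12)
        Q, shift = _random_rigid(rng)
        assert radius_of_gyration(pts @ Q.T + shift, m) == pytest.approx(
            radius_of_gyration(pts, m), rel=1e-12
        )

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            radius_of_gyration([[0, 0, 0]], [0.0])


class TestRmsf:
    def test_static_trajectory_zero(self):
        traj, _ = gen_trajectory("static", {"n_frames": 10}, seed=1)
        assert rmsf_per_atom(traj).max() < 1e-12

    def test_two_frame_oscillation_closed_form(self, rng):
        base = rng.normal(size=(6, 3))
        a = 0.07
        up, down = base.copy(), base.copy()
        up[2, 0] += a
        down[2, 0] -= a
        vals = rmsf_per_atom(_traj([up, down]), superpose=False)
        assert vals[2] == pytest.approx(a, rel=1e-12)
        assert np.delete(vals, 2).max() == 0.0

    def test_gaussian_jitter_converges_to_sigma_sqrt3(self, rng):
        sigma = 0.02
        base = rng.normal(size=(4, 3))
        frames = base[None] + sigma * rng.standard_normal((2000, 4, 3))
        vals = rmsf_per_atom(_traj(frames), superpose=False)
        assert vals == pytest.approx(sigma * np.sqrt(3.0), rel=0.05)

    def test_wobble_truth_and_residue_aggregation(self):
        traj, truth = gen_trajectory(
            "wobble", {"n_atoms": 8, "n_frames": 64, "amplitude": 0.04}, seed=5
        )
        vals = rmsf_per_atom(traj, superpose=False)
        assert np.abs(vals - truth["rmsf_raw"]).max() < 1e-9
        ids, res_vals = rmsf_per_residue(traj, vals)
        assert len(ids) == 8 and res_vals == pytest.approx(vals)

    def test_single_frame_rejected(self, rng):
        with pytest.raises(ValueError, match="2 frames"):
            rmsf_per_atom(_traj(rng.normal(size=(1, 5, 3))))


class TestGromosCluster:
    def test_identical_frames_single_cluster(self):
        traj, _ = gen_trajectory("static", {"n_frames": 12}, seed=3)
        res = gromos_cluster(traj, cutoff=0.1)
        assert res.n_clusters == 1
        assert np.all(res.assignments == 0)

    def test_two_state_trajectory(self):
        traj, truth = gen_trajectory(
            "two_state", {"separation": 0.5, "n_frames": 30}, seed=4
        )
        res = gromos_cluster(traj, cutoff=0.1)
        assert res.n_clusters == truth["n_clusters"] == 2
        labels = truth["state_labels"]
        for cid in (0, 1):
            assert len(set(labels[res.assignments == cid])) == 1
        for cid, rep in res.representatives.items():
            assert res.assignments[rep] == cid

    def test_huge_cutoff_single_cluster(self, rng):
        traj = _traj(rng.normal(size=(6, 5, 3)))
        assert gromos_cluster(traj, cutoff=100.0).n_clusters == 1

    def test_cluster_count_nonincreasing_in_cutoff(self):
        traj, _ = gen_trajectory(
            "two_state", {"separation": 0.4, "n_frames": 20, "jitter": 0.05}, seed=6
        )
        counts = [
            gromos_cluster(traj, cutoff=c).n_clusters
            for c in (0.02, 0.05, 0.1, 0.2, 0.5, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_positive_cutoff_required(self, rng):
        with pytest.raises(ValueError, match="positive"):
            gromos_cluster(_traj(rng.normal(size=(2, 4, 3))), cutoff=0.0)


def test_rmsd_pseudometric_on_sampled_triples(rng):
    frames = rng.normal(size=(6, 7, 3))
    traj = _traj(frames)
    from flavodesc.trajectory import pairwise_rmsd_matrix

    M = pairwise_rmsd_matrix(traj)
    assert M == pytest.approx(M.T, abs=1e-12)
    assert np.all(np.diag(M) == 0.0)
    for i in range(6):
        for j in range(6):
            for k in range(6):
                assert M[i, j] <= M[i, k] + M[k, j] + 1e-9
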