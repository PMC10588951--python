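"""Superposition RMSD, RMSF, interdimer distance and dissociation calls."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from scassembly.core_model import Trajectory
from scassembly.traj_analysis import (
    detect_dissociation,
    interdimer_distance,
    interdimer_distance_series,
    kabsch_superpose,
    rmsd_series,
    rmsf,
)


def brute_force_min_rmsd(X, Y, n_coarse=20000, seed=0):
    """Independent oracle: coarse random rotation search + local refinement
    of the rotation vector with a generic optimizer (no SVD closed form)."""
    from scipy.optimize import minimize

    X0 = X - X.mean(axis=0)
    Y0 = Y - Y.mean(axis=0)

    def rmsd_of(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = X0 @ R.T - Y0
        return np.sqrt((d * d).sum(axis=1).mean())

    rng = np.random.default_rng(seed)
    cand = Rotation.random(n_coarse, random_state=rng).as_rotvec()
    vals = np.array([rmsd_of(v) for v in cand])
    best = cand[np.argmin(vals)]
    res = minimize(rmsd_of, best, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
    return res.fun


class TestKabsch:
    def test_self_superposition(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        R, t, rmsd = kabsch_superpose(X, X)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)

    def test_rigid_motion_removed(self):
        X = np.random.default_rng(1).normal(size=(5, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Y = X @ Rz.T + np.array([5.0, 0.0, 0.0])
        _, _, rmsd = kabsch_superpose(X, Y)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert rmsd <= np.sqrt(((X - Y) ** 2).sum(axis=1).mean()) + 1e-12

    def test_matches_brute_force_on_noisy_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(3):
            X = rng.normal(size=(4, 3)) * 2.0
            R = Rotation.random(random_state=rng).as_matrix()
            Y = X @ R.T + rng.normal(scale=0.5, size=(4, 3))
            _, _, rmsd = kabsch_superpose(X, Y)
            oracle = brute_force_min_rmsd(X, Y, seed=1)
            assert rmsd == pytest.approx(oracle, abs=1e-3)

    def test_proper_rotation(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 3))
        Y = -X  # a reflection would fit perfectly but is not allowed
        R, _, _ = kabsch_superpose(X, Y)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-8)

    def test_shape_and_count_validation(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestRmsdSeries:
    def test_reference_frame_is_zero(self):
        rng = np.random.default_rng(0)
        traj = Trajectory(coords=rng.normal(size=(4, 6, 3)), time_per_frame=1.0)
        _, series = rmsd_series(traj, reference_frame=0)
        assert series[0] == pytest.approx(0.0, abs=1e-10)

    def test_rigid_translations_give_zero(self):
        base = np.random.default_rng(1).normal(size=(6, 3))
        frames = np.stack([base + k * np.array([1.0, 2.0, 0.5]) for k in range(5)])
        traj = Trajectory(coords=frames, time_per_frame=1.0)
        _, series = rmsd_series(traj)
        np.testing.assert_allclose(series, 0.0, atol=1e-10)

    def test_balanced_displacement_hand_value(self):
        """Four beads on a square displaced +/-a along z: zero net
        translation and torque, so the optimal transform is the identity
        and RMSD = a exactly."""
        a = 3.0
        sq = np.array([[1, 1, 0], [1, -1, 0], [-1, -1, 0], [-1, 1, 0]], dtype=float)
        frame2 = sq + np.array([[0, 0, a], [0, 0, -a], [0, 0, a], [0, 0, -a]])
        traj = Trajectory(coords=np.stack([sq, frame2]), time_per_frame=1.0)
        _, series = rmsd_series(traj)
        assert series[1] == pytest.approx(a, abs=1e-8)

    def test_single_displaced_particle_hand_value(self):
        """One particle at the centroid of a symmetric anchor set displaced
        by d: after re-centering, RMSD = sqrt(d^2/N * (1 - 1/N))."""
        d = 3.0
        anchors = np.array(
            [[10, 0, 0], [-10, 0, 0], [0, 10, 0], [0, -10, 0],
             [0, 0, 10], [0, 0, -10]], dtype=float)
        frame1 = np.vstack([anchors, [[0.0, 0.0, 0.0]]])
        frame2 = frame1.copy()
        frame2[-1, 2] += d
        n = frame1.shape[0]
        traj = Trajectory(coords=np.stack([frame1, frame2]), time_per_frame=1.0)
        _, series = rmsd_series(traj)
        expected = np.sqrt(d**2 / n * (1 - 1 / n))
        assert series[1] == pytest.approx(expected, abs=1e-8)

    def test_empty_selection_raises(self):
        traj = Trajectory(coords=np.zeros((2, 5, 3)), time_per_frame=1.0)
        with pytest.raises(ValueError):
            rmsd_series(traj, selection=np.array([], dtype=int))


class TestRmsf:
    def test_static_trajectory_zero(self):
        frames = np.repeat(np.random.default_rng(0).normal(size=(1, 7, 3)), 5, axis=0)
        traj = Trajectory(coords=frames, time_per_frame=1.0)
        np.testing.assert_allclose(rmsf(traj), 0.0, atol=1e-12)

    def test_alternating_bead_two_point_variance(self):
        """A bead alternating between +a and -a about its mean has RMSF a."""
        a = 2.0
        anchors = np.array([[10, 0, 0], [-10, 0, 0], [0, 10, 0], [0, -10, 0]],
                           dtype=float)
        up = np.vstack([anchors, [[0, 0, a]]])
        dn = np.vstack([anchors, [[0, 0, -a]]])
        traj = Trajectory(coords=np.stack([up, dn, up, dn]), time_per_frame=1.0)
        vals = rmsf(traj, align_to_mean=False)
        np.testing.assert_allclose(vals[:4], 0.0, atol=1e-12)
        assert vals[4] == pytest.approx(a)

    def test_isotropic_jitter_closed_form(self):
        """Isotropic Gaussian jitter of per-coordinate sigma gives
        RMSF -> sigma * sqrt(3)."""
        rng = np.random.default_rng(7)
        sigma = 0.8
        base = rng.normal(size=(1, 30, 3)) * 5
        frames = base + rng.normal(scale=sigma, size=(8000, 30, 3))
        traj = Trajectory(coords=frames, time_per_frame=1.0)
        vals = rmsf(traj, align_to_mean=False)
        assert np.mean(vals) == pytest.approx(sigma * np.sqrt(3), rel=0.03)

    def test_single_frame_raises(self):
        traj = Trajectory(coords=np.zeros((1, 5, 3)), time_per_frame=1.0)
        with pytest.raises(ValueError):
            rmsf(traj)


class TestInterdimerDistance:
    def test_direct_distance(self, tetramer):
        coords = tetramer.coords.copy()
        idx1 = np.intersect1d(tetramer.dimer_particles("dimer1"),
                              tetramer.particle_indices(residue=109))
        idx2 = np.intersect1d(tetramer.dimer_particles("dimer2"),
                              tetramer.particle_indices(residue=109))
        coords[idx1] = [0.0, 0.0, 0.0]
        coords[idx2] = [0.0, 0.0, 6.0]
        assert interdimer_distance(coords, tetramer) == pytest.approx(6.0)
        # collinear translation of dimer2 by +50 A
        coords2 = coords.copy()
        coords2[tetramer.dimer_particles("dimer2")] += [0.0, 0.0, 50.0]
        assert interdimer_distance(coords2, tetramer) == pytest.approx(56.0)

    def test_rigid_motion_invariance(self, tetramer):
        from scipy.spatial.transform import Rotation

        d0 = interdimer_distance(tetramer.coords, tetramer)
        R = Rotation.from_euler("zyx", [10, 20, 30], degrees=True).as_matrix()
        moved = tetramer.coords @ R.T + np.array([100.0, -3.0, 7.0])
        assert interdimer_distance(moved, tetramer) == pytest.approx(d0)

    def test_marker_absent_raises(self, tetramer):
        import copy

        broken = copy.deepcopy(tetramer)
        broken.marker_residue = 500
        with pytest.raises(ValueError, match="marker"):
            interdimer_distance(broken.coords, broken)


class TestDetectDissociation:
    def test_constant_low_is_intact(self):
        t = np.arange(100.0)
        r = detect_dissociation(t, np.full(100, 7.0))
        assert r.status == "intact" and r.disruption_time is None

    def test_step_function_dissociates_at_step(self):
        t = np.arange(0.0, 100.0, 1.0)
        d = np.where(t < 50.0, 7.0, 40.0)
        r = detect_dissociation(t, d, dissociated_threshold=30.0)
        assert r.status == "dissociated"
        assert r.disruption_time == pytest.approx(50.0, abs=1.0)

    def test_oscillating_series_is_loosened(self):
        t = np.arange(0.0, 100.0, 0.5)
        d = 11.5 + 3.5 * np.sin(t * 2.0)  # oscillates 8-15 A
        r = detect_dissociation(t, d, dissociated_threshold=30.0)
        assert r.status == "loosened" and r.disruption_time is None

    def test_transient_spike_is_not_dissociation(self):
        t = np.arange(0.0, 100.0, 1.0)
        d = np.full_like(t, 7.0)
        d[40] = 45.0  # single-frame excursion, returns below intact
        r = detect_dissociation(t, d)
        assert r.status == "intact"

    def test_resampling_stability(self):
        """A finer sampling of the same signal moves the disruption time by
        at most one coarse sample."""
        f = lambda t: np.where(t < 42.0, 6.0, 38.0)
        t1 = np.arange(0.0, 100.0, 1.0)
        t2 = np.arange(0.0, 100.0, 0.2)
        r1 = detect_dissociation(t1, f(t1))
        r2 = detect_dissociation(t2, f(t2))
        assert r1.status == r2.status == "dissociated"
        assert abs(r1.disruption_time - r2.disruption_time) <= 1.0

    def test_non_monotone_times_raise(self):
        with pytest.raises(ValueError, match="increasing"):
            detect_dissociation(np.array([0.0, 2.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    def test_status_invariant_on_result(self):
        from scassembly.traj_analysis import DissociationResult

        with pytest.raises(ValueError):
            DissociationResult(status="dissociated", disruption_time=None,
                               times=np.array([0.0]), distances=np.array([1.0]))
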