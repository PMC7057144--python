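"""Superposition, RMSD series, contacts and the energy landscape."""

import numpy as np
import pytest

from sumd.analysis import (
    DegeneracyError,
    contact_fingerprint,
    energy_landscape,
    kabsch_superpose,
    ligand_rmsd_series,
    moving_average,
    target_rmsd_series,
)
from sumd.supervision import Trajectory

from conftest import simple_topology


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()


def quaternion_rmsd(P, Q):
    """Independent optimal-superposition RMSD via the quaternion (Horn)
    eigenvalue method."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    S = P.T @ Q
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    msd = max(0.0, ((P**2).sum() + (Q**2).sum() - 2.0 * lam)) / len(P)
    return np.sqrt(msd)


def traj_from(frames, times=None):
    t = Trajectory()
    for i, f in enumerate(frames):
        t.append(times[i] if times else float(i), f, 0)
    return t


class TestKabsch:
    def test_identity_on_equal_sets(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        R, t, moved = kabsch_superpose(X, X)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(moved, X, atol=1e-12)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 3))
        R0 = random_rotation(rng)
        Y = X @ R0.T + np.array([3.0, -1.0, 7.0])
        R, t, moved = kabsch_superpose(Y, X)
        assert np.linalg.det(R) == pytest.approx(1.0)
        assert np.sqrt(((moved - X) ** 2).sum(axis=1).mean()) < 1e-8

    def test_agrees_with_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            P = rng.normal(size=(10, 3))
            Q = rng.normal(size=(10, 3))
            _, _, moved = kabsch_superpose(P, Q)
            fit_rmsd = np.sqrt(((moved - Q) ** 2).sum(axis=1).mean())
            assert fit_rmsd == pytest.approx(quaternion_rmsd(P, Q), abs=1e-8)

    def test_collinear_selection_rejected(self):
        X = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegeneracyError):
            kabsch_superpose(X, X + 1.0)

    def test_proper_rotation_even_for_reflected_input(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 3))
        Y = X.copy()
        Y[:, 0] *= -1.0  # a reflection
        R, _, _ = kabsch_superpose(Y, X)
        assert np.linalg.det(R) == pytest.approx(1.0)


@pytest.fixture
def toy_complex():
    """5 target atoms + 2 ligand atoms with a well-defined reference pose."""
    topo = simple_topology(n_target=5, n_ligand=2)
    rng = np.random.default_rng(7)
    ref = rng.normal(scale=4.0, size=(7, 3))
    return topo, ref


class TestLigandRMSD:
    def test_reference_trajectory_is_all_zero(self, toy_complex):
        topo, ref = toy_complex
        series = ligand_rmsd_series(traj_from([ref.copy()] * 3), ref, topo)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-10)
        assert series.rmsd_min == pytest.approx(0.0, abs=1e-10)

    def test_rigidly_offset_ligand_gives_constant_series(self, toy_complex):
        topo, ref = toy_complex
        d = 2.5
        frame = ref.copy()
        frame[topo.ligand_index] += np.array([0.0, 0.0, d])
        series = ligand_rmsd_series(traj_from([frame] * 4), ref, topo)
        np.testing.assert_allclose(series.values, d, atol=1e-9)

    def test_matches_per_frame_brute_force(self, toy_complex):
        """Three arbitrary frames agree with superpose-then-direct-formula."""
        topo, ref = toy_complex
        rng = np.random.default_rng(11)
        frames = [ref + rng.normal(scale=0.8, size=ref.shape) for _ in range(3)]
        series = ligand_rmsd_series(traj_from(frames), ref, topo)
        fit = topo.target_index
        lig = topo.ligand_index
        for f, pos in enumerate(frames):
            _, _, moved = kabsch_superpose(pos, ref, fit)
            expected = np.sqrt(((moved[lig] - ref[lig]) ** 2).sum(axis=1).mean())
            assert series.values[f] == pytest.approx(expected, abs=1e-12)

    def test_global_rigid_transform_invariance(self, toy_complex):
        topo, ref = toy_complex
        rng = np.random.default_rng(13)
        frame = ref + rng.normal(scale=0.5, size=ref.shape)
        base = ligand_rmsd_series(traj_from([frame]), ref, topo).values[0]
        R = random_rotation(rng)
        moved = frame @ R.T + np.array([8.0, -2.0, 4.0])
        transformed = ligand_rmsd_series(traj_from([moved]), ref, topo).values[0]
        assert transformed == pytest.approx(base, abs=1e-8)

    def test_multi_model_reference_takes_minimum(self, toy_complex):
        topo, ref = toy_complex
        far = ref.copy()
        far[topo.ligand_index] += 10.0
        models = np.stack([far, ref])
        series = ligand_rmsd_series(traj_from([ref.copy()]), models, topo)
        assert series.values[0] == pytest.approx(0.0, abs=1e-9)
        assert series.per_model.shape == (1, 2)

    def test_summary_consistency(self, toy_complex):
        topo, ref = toy_complex
        rng = np.random.default_rng(17)
        frames = [ref + rng.normal(scale=s, size=ref.shape)
                  for s in (0.1, 1.0, 0.4)]
        series = ligand_rmsd_series(traj_from(frames), ref, topo)
        assert series.rmsd_min <= series.values.min() + 1e-15
        assert series.rmsd_max >= series.values.max() - 1e-15
        assert series.values[series.argmin_frame] == series.rmsd_min


class TestTargetRMSD:
    def test_frozen_target_all_zero(self, toy_complex):
        topo, ref = toy_complex
        frames = []
        rng = np.random.default_rng(19)
        for _ in range(3):
            f = ref.copy()
            f[topo.ligand_index] += rng.normal(size=(2, 3))  # ligand moves
            frames.append(f)
        series = target_rmsd_series(traj_from(frames), topo)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-10)

    def test_single_displaced_atom_without_refit(self, toy_complex):
        """One atom displaced by 1 A among N: RMSD = 1/sqrt(N) unfitted."""
        topo, ref = toy_complex
        frame = ref.copy()
        frame[0] += np.array([1.0, 0.0, 0.0])
        n = len(topo.target_index)
        series = target_rmsd_series(
            traj_from([frame]), topo, reference=ref, superpose=False
        )
        assert series.values[0] == pytest.approx(1.0 / np.sqrt(n), abs=1e-12)

    def test_restrained_run_stays_near_reference(self, funnel):
        """With 1 kcal/mol/A^2 restraints the target RMSD stays bounded."""
        from sumd.core import EnergyParams, EngineConfig
        from sumd.engine import LangevinEngine

        topo, _, start, _ = funnel
        cfg = EngineConfig(
            dt=0.02, friction=10.0, restraint_k=1.0,
            target_mobility="restrained",
        )
        eng = LangevinEngine(topo, cfg, EnergyParams(),
                             restraint_reference=start.positions)
        s = start.copy()
        s.rng_state = np.random.PCG64(23).state
        s = eng.resample(s)
        frames, times = [], []
        for k in range(10):
            s, _ = eng.advance(s, 250)
            frames.append(s.positions.copy())
            times.append(s.time)
        series = target_rmsd_series(
            traj_from(frames, times), topo, reference=start.positions
        )
        assert series.rmsd_max < 2.0


class TestContacts:
    def _one_frame(self, lig_x):
        topo = simple_topology(n_target=2, n_ligand=1)
        pos = np.array([[0.0, 0, 0], [20.0, 0, 0], [lig_x, 0.0, 0.0]])
        return topo, traj_from([pos])

    def test_inside_cutoff_counts(self):
        topo, traj = self._one_frame(3.9)
        fp = contact_fingerprint(traj, topo, cutoff=4.0)
        assert fp.counts[0, 0] == 1
        assert fp.contacted[0, 0]

    def test_outside_cutoff_does_not_count(self):
        topo, traj = self._one_frame(4.1)
        fp = contact_fingerprint(traj, topo, cutoff=4.0)
        assert fp.counts[0, 0] == 0

    def test_matches_brute_force_on_bound_pose(self, funnel):
        topo, bound, _, _ = funnel
        traj = traj_from([bound.positions])
        fp = contact_fingerprint(traj, topo, cutoff=4.0)
        # brute force: all-pairs distance matrix
        lig = topo.ligand_index
        contacted = set()
        for j in topo.target_index:
            dmin = min(
                np.linalg.norm(bound.positions[i] - bound.positions[j])
                for i in lig
            )
            if dmin <= 4.0:
                contacted.add(int(topo.group_id[j]))
        reported = {
            int(g) for k, g in enumerate(fp.group_ids) if fp.contacted[0, k]
        }
        assert reported == contacted
        assert len(contacted) > 0  # the bound pose really touches the cleft

    def test_frequency_monotone_in_cutoff(self, funnel):
        topo, bound, start, _ = funnel
        traj = traj_from([bound.positions, start.positions])
        f1 = contact_fingerprint(traj, topo, cutoff=3.0).frequency
        f2 = contact_fingerprint(traj, topo, cutoff=4.0).frequency
        f3 = contact_fingerprint(traj, topo, cutoff=6.0).frequency
        assert np.all(f1 <= f2) and np.all(f2 <= f3)

    def test_most_contacted_ordering(self, funnel):
        topo, bound, _, _ = funnel
        fp = contact_fingerprint(traj_from([bound.positions]), topo)
        ranked = fp.most_contacted()
        freqs = [f for _, _, f in ranked]
        assert freqs == sorted(freqs, reverse=True)


class TestLandscape:
    def test_single_frame_single_bin(self):
        grid = energy_landscape([7.0], [-3.0])
        assert grid.counts.sum() == 1
        i, j = np.argwhere(grid.counts == 1)[0]
        assert grid.mean_energy[i, j] == pytest.approx(-3.0)

    def test_count_conservation_across_bins(self):
        d = [1.0, 1.1, 1.2, 9.0, 9.1]
        e = [0.0] * 5
        grid = energy_landscape(d, e, distance_edges=np.array([0, 5, 10.0]),
                                energy_edges=np.array([-1, 1.0]))
        assert list(grid.distance_marginal()) == [3, 2]
        assert grid.n_frames == 5

    def test_empty_bins_flagged_nan_not_zero(self):
        grid = energy_landscape([1.0, 9.0], [0.0, 0.0],
                                distance_edges=np.array([0, 4, 6, 10.0]),
                                energy_edges=np.array([-1, 1.0]))
        assert np.isnan(grid.mean_energy[1, 0])
        assert grid.mean_energy[0, 0] == 0.0

    def test_bin_means_match_brute_force(self, funnel):
        """Per-bin means equal regrouping the frames by bin by hand."""
        rng = np.random.default_rng(29)
        d = rng.uniform(2, 30, 200)
        e = rng.normal(-5, 3, 200)
        grid = energy_landscape(d, e, distance_edges=8, energy_edges=6)
        for i in range(len(grid.distance_edges) - 1):
            for j in range(len(grid.energy_edges) - 1):
                mask = (
                    (d >= grid.distance_edges[i]) & (d < grid.distance_edges[i + 1])
                    & (e >= grid.energy_edges[j]) & (e < grid.energy_edges[j + 1])
                )
                if grid.counts[i, j] > 0:
                    assert grid.counts[i, j] == mask.sum()
                    assert grid.mean_energy[i, j] == pytest.approx(e[mask].mean())
        assert grid.n_frames == 200

    def test_marginal_equals_1d_histogram(self):
        rng = np.random.default_rng(31)
        d = rng.uniform(0, 20, 500)
        e = rng.normal(size=500)
        edges = np.linspace(0, 20.000001, 11)
        grid = energy_landscape(d, e, distance_edges=edges, energy_edges=5)
        hist, _ = np.histogram(d, bins=edges)
        np.testing.assert_array_equal(grid.distance_marginal(), hist)

    def test_non_finite_input_named(self):
        with pytest.raises(Exception, match="frame 1"):
            energy_landscape([1.0, np.nan], [0.0, 0.0])


class TestMovingAverage:
    def test_width_one_is_identity(self):
        x = np.array([1.0, 4.0, 2.0])
        np.testing.assert_allclose(moving_average(x, 1), x)

    def test_constant_series_unchanged(self):
        x = np.full(10, 3.3)
        np.testing.assert_allclose(moving_average(x, 5), x)
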