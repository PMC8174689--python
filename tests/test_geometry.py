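import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import nucbreathe as nb


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t


class TestSuperpose:
    @pytest.fixture(scope="class")
    def cloud(self):
        return np.random.default_rng(0).normal(0, 10, (50, 3))

    def test_identity(self, cloud):
        transform, rmsd = nb.superpose(cloud, cloud)
        assert rmsd <= 1e-9
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-9)

    def test_recovers_constructed_transform(self, cloud):
        R = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        t = np.array([5.0, -3.0, 2.0])
        mobile = cloud @ R.T + t
        transform, rmsd = nb.superpose(mobile, cloud)
        assert rmsd <= 1e-6
        assert np.abs(transform.rotation - R.T).max() <= 1e-6
        assert np.abs(transform.apply(mobile) - cloud).max() <= 1e-6

    def test_noisy_fit_matches_independent_oracle(self, cloud):
        """Cross-check the minimized RMSD against MDAnalysis' Kabsch fit."""
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        noisy = cloud + np.random.default_rng(1).normal(0, 0.5, cloud.shape)
        _, ours = nb.superpose(noisy, cloud)
        oracle = mda_rmsd(noisy, cloud, center=True, superposition=True)
        assert abs(ours - oracle) / oracle <= 0.05

    def test_degenerate_selections_raise(self):
        line = np.outer(np.arange(5.0), [1.0, 2.0, 0.5])
        with pytest.raises(nb.GeometryError):
            nb.superpose(line, line + 1.0)
        two = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        with pytest.raises(nb.GeometryError):
            nb.superpose(two, two)


class TestDyadFrame:
    def test_matches_generator_axes(self, ideal, nuc):
        structure, truth = ideal
        frame = nb.build_dyad_frame(structure.coordinates, nuc)
        gen = truth.dyad_frame()
        for ax in ("X", "Y", "Z"):
            cosang = np.clip(getattr(frame, ax) @ getattr(gen, ax), -1, 1)
            assert np.degrees(np.arccos(cosang)) <= 1.0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_equivariance_under_rigid_transform(self, ideal, nuc, seed):
        structure, _ = ideal
        R, t = random_rigid(seed)
        frame0 = nb.build_dyad_frame(structure.coordinates, nuc)
        frame1 = nb.build_dyad_frame(structure.coordinates @ R.T + t, nuc)
        for ax in ("X", "Y", "Z"):
            assert np.abs(frame1.__dict__[ax] - R @ frame0.__dict__[ax]).max() <= 1e-6
        assert np.abs(frame1.origin - (R @ frame0.origin + t)).max() <= 1e-6

    def test_orthonormal_right_handed(self, ideal, nuc, step_traj):
        structure, _ = ideal
        frames = [nb.build_dyad_frame(structure.coordinates, nuc)]
        traj, _ = step_traj
        frames.append(nb.build_dyad_frame(traj.coords[45], nuc))
        for f in frames:
            M = np.stack([f.X, f.Y, f.Z])
            assert np.abs(M @ M.T - np.eye(3)).max() <= 1e-9
            assert np.abs(np.cross(f.X, f.Y) - f.Z).max() <= 1e-9

    def test_collinear_bp_centers_raise(self):
        centers = np.outer(np.arange(100.0), [1.0, 0, 0])
        with pytest.raises(nb.GeometryError):
            nb.frame_from_bp_centers(centers, np.arange(20, 80), 50)


class TestArmVector:
    def test_straight_linker_along_known_direction(self, ideal, nuc, spec):
        structure, truth = ideal
        gen = truth.dyad_frame()
        th = np.radians(spec.arm_elevation_deg)
        d = np.sin(th) * gen.Y + np.cos(th) * gen.Z
        for arm in ("3p", "5p"):
            v = nb.arm_vector(structure.coordinates, nuc, arm)
            assert v @ d >= 0.999

    def test_endpoint_mode_agrees_on_straight_arm(self, ideal, nuc):
        structure, _ = ideal
        v1 = nb.arm_vector(structure.coordinates, nuc, "3p", mode="tls")
        v2 = nb.arm_vector(structure.coordinates, nuc, "3p", mode="endpoints")
        assert v1 @ v2 >= 1 - 1e-9

    def test_coincident_centers_raise(self, ideal, nuc):
        structure, _ = ideal
        coords = structure.coordinates.copy()
        arm_atoms = nuc.bp_atoms(nuc.annotation.arm_range_3p, heavy_only=False)
        coords[arm_atoms] = coords[arm_atoms[0]]
        with pytest.raises(nb.GeometryError):
            nb.arm_vector(coords, nuc, "3p")


class TestComputeGamma:
    def _with_arm_along(self, structure, nuc, direction):
        """Rebuild the 3' linker so its bp centers run along ``direction``."""
        coords = structure.coordinates.copy()
        ann = nuc.annotation
        frame = nb.build_dyad_frame(coords, nuc)
        d = (direction[0] * frame.X + direction[1] * frame.Y
             + direction[2] * frame.Z)
        start = nuc.bp_centers(coords)[ann.arm_range_3p[0] - 1]
        for k, bp in enumerate(ann.arm_range_3p):
            for atom in (nuc.bp_ref_sense[bp - 1], nuc.bp_ref_anti[bp - 1]):
                coords[atom] = start + 3.3 * k * d
        return coords, frame

    def test_arm_along_z_gives_zero_gamma1(self, ideal, nuc):
        structure, _ = ideal
        coords, frame = self._with_arm_along(structure, nuc, (0, 0, 1))
        g1, _ = nb.compute_gamma(coords, nuc, frame, "3p")
        assert abs(g1) <= 1e-6

    def test_tilted_arm_closed_form(self, ideal, nuc):
        structure, _ = ideal
        d = (np.sin(np.radians(30)), 0.0, np.cos(np.radians(30)))
        coords, frame = self._with_arm_along(structure, nuc, d)
        g1, g2 = nb.compute_gamma(coords, nuc, frame, "3p")
        assert abs(g1 - 30.0) <= 1e-6
        assert abs(abs(g2) - 90.0) <= 1e-6

    def test_recovery_against_ground_truth(self, step_traj, nuc):
        traj, truth = step_traj
        obs = nb.breathing_series(traj, nuc)
        for arm in ("3p", "5p"):
            for j, col in enumerate((f"gamma1_{arm}", f"gamma2_{arm}")):
                err = obs[col].to_numpy() - truth.gamma[arm][:, j]
                assert np.sqrt(np.mean(err ** 2)) <= 2.0

    def test_rigid_motion_invariance(self, step_traj, nuc):
        traj, _ = step_traj
        obs0 = nb.breathing_series(traj, nuc)
        R, t = random_rigid(9)
        moved = nb.Trajectory(traj.topology, traj.coords[:10] @ R.T + t,
                              traj.frame_interval)
        obs1 = nb.breathing_series(moved, nuc)
        for col in ("gamma1_3p", "gamma2_3p", "gamma1_5p", "gamma2_5p", "rg"):
            assert np.abs(obs1[col].to_numpy()
                          - obs0[col].to_numpy()[:10]).max() <= 1e-6


class TestRg:
    def test_points_on_circle(self):
        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        pts = 7.5 * np.stack([np.cos(th), np.sin(th), np.zeros_like(th)], axis=1)
        assert abs(nb.compute_rg(pts) - 7.5) <= 7.5 * 1e-9

    def test_square_corners(self):
        pts = np.array([[0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0]], float)
        assert abs(nb.compute_rg(pts) - np.sqrt(2)) <= 1e-12

    def test_open_exceeds_closed(self, nuc):
        spec = nb.SyntheticSpec(jitter_sigma=0.0)
        closed, _ = nb.make_breathing_trajectory(
            spec, {"3p": np.zeros((1, 2)), "5p": np.zeros((1, 2))}, seed=0)
        opened, _ = nb.make_breathing_trajectory(
            spec, {"3p": np.full((1, 2), 35.0), "5p": np.full((1, 2), 35.0)},
            seed=0)
        dna = nuc.dna_heavy_atoms()
        m = closed.topology.masses
        assert (nb.compute_rg(opened.coords[0], dna, m)
                > nb.compute_rg(closed.coords[0], dna, m))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_bruteforce_definition(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 5, (rng.integers(2, 40), 3))
        w = rng.uniform(0.5, 2.0, pts.shape[0])
        ctr = (pts * w[:, None]).sum(0) / w.sum()
        expected = np.sqrt(sum(wi * ((p - ctr) ** 2).sum()
                               for wi, p in zip(w, pts)) / w.sum())
        got = nb.compute_rg(pts, masses=w, mass_weighted=True)
        assert abs(got - expected) <= 1e-9 * max(expected, 1)

    def test_empty_selection_raises(self):
        with pytest.raises(nb.SelectionError):
            nb.compute_rg(np.zeros((5, 3)), np.array([], dtype=int))


class TestGammaHistogram:
    @staticmethod
    def _df(g1, g2):
        return pd.DataFrame({"gamma1_3p": g1, "gamma2_3p": g2})

    def test_single_bin_area(self):
        h = nb.gamma_histogram2d(self._df([12.0] * 40, [-3.0] * 40), "3p",
                                 bin_width=2.5)
        assert h.occupied_area == pytest.approx(6.25)
        assert h.n_frames == 40

    def test_k_distinct_bins(self):
        g1 = np.arange(8) * 10.0  # 8 well-separated bins
        h = nb.gamma_histogram2d(self._df(g1, np.zeros(8)), "3p",
                                 bin_width=2.5, occupancy_min=1)
        assert h.occupied_area == pytest.approx(8 * 6.25)

    def test_gaussian_mode_near_sample_mean(self):
        rng = np.random.default_rng(4)
        g1 = rng.normal(20.0, 5.0, 10_000)
        g2 = rng.normal(-10.0, 5.0, 10_000)
        h = nb.gamma_histogram2d(self._df(g1, g2), "3p", bin_width=2.5)
        assert abs(h.mode_bin[0] - g1.mean()) <= 2.5
        assert abs(h.mode_bin[1] - g2.mean()) <= 2.5

    def test_nonpositive_bin_width_raises(self):
        with pytest.raises(ValueError):
            nb.gamma_histogram2d(self._df([1.0], [1.0]), "3p", bin_width=0)
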