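import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nucbreathe as nb
from nucbreathe import ContactSpec, WeightedDistanceSpec


def brute_force_contacts(a, b, cutoff):
    """Independent O(N^2) oracle: plain double loop."""
    count = 0
    for pa in a:
        for pb in b:
            if np.sqrt(((pa - pb) ** 2).sum()) < cutoff:
                count += 1
    return count


class TestContacts:
    def _pair(self, d):
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        return coords, np.array([0]), np.array([1])

    def test_strict_cutoff(self):
        coords, a, b = self._pair(4.49)
        assert nb.count_contacts(coords, a, b) == 1
        coords, a, b = self._pair(4.51)
        assert nb.count_contacts(coords, a, b) == 0
        coords, a, b = self._pair(4.5)
        assert nb.count_contacts(coords, a, b) == 0  # strictly less than

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 15, (40, 3))
        b = rng.uniform(0, 15, (40, 3))
        coords = np.vstack([a, b])
        ia, ib = np.arange(40), np.arange(40, 80)
        expected = brute_force_contacts(a, b, 4.5)
        assert nb.count_contacts(coords, ia, ib) == expected
        assert nb.count_contacts(coords, ib, ia) == expected  # symmetric

    def test_empty_or_overlapping_selection_raises(self):
        coords = np.zeros((4, 3))
        with pytest.raises(nb.SelectionError):
            nb.count_contacts(coords, np.array([], dtype=int), np.array([1]))
        with pytest.raises(nb.SelectionError):
            nb.count_contacts(coords, np.array([0, 1]), np.array([1, 2]))


class TestWeightedMeanDistance:
    def test_single_atom_groups_any_exponent(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        for n in (2, 10, 100):
            got = nb.weighted_mean_distance(coords, [0], [1],
                                            WeightedDistanceSpec(n))
            assert got == pytest.approx(5.0, abs=1e-12)

    def test_hand_evaluated_three_atom_case(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]])
        got = nb.weighted_mean_distance(coords, [0], [1, 2],
                                        WeightedDistanceSpec(2))
        # ((1/2)(1/4 + 1/16))^(-1/2)
        assert got == pytest.approx(2.5298221281347035, abs=1e-9)

    def test_n100_bias_bound_at_20v20(self):
        """d[100] sits between the true minimum and min*(N1*N2)^(1/100)."""
        from scipy.spatial.distance import cdist

        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.uniform(0, 30, (20, 3))
            b = rng.uniform(5, 40, (20, 3))
            coords = np.vstack([a, b])
            dmin = cdist(a, b).min()
            got = nb.weighted_mean_distance(coords, np.arange(20),
                                            np.arange(20, 40),
                                            WeightedDistanceSpec(100))
            assert dmin - 1e-12 <= got <= dmin * 400 ** 0.01 + 1e-12

    def test_small_groups_approach_minimum_within_2pct(self):
        from scipy.spatial.distance import cdist

        rng = np.random.default_rng(1)
        for _ in range(100):
            n1, n2 = rng.integers(1, 3), rng.integers(1, 3)
            a = rng.uniform(0, 30, (n1, 3))
            b = rng.uniform(5, 40, (n2, 3))
            coords = np.vstack([a, b])
            dmin = cdist(a, b).min()
            got = nb.weighted_mean_distance(coords, np.arange(n1),
                                            np.arange(n1, n1 + n2),
                                            WeightedDistanceSpec(100))
            assert abs(got - dmin) / dmin <= 0.02

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_power_mean_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(1, 15), rng.integers(1, 15)
        a = rng.uniform(0, 20, (n1, 3))
        b = rng.uniform(3, 25, (n2, 3))
        coords = np.vstack([a, b])
        ia, ib = np.arange(n1), np.arange(n1, n1 + n2)
        from scipy.spatial.distance import cdist

        dmin = cdist(a, b).min()
        vals = [nb.weighted_mean_distance(coords, ia, ib,
                                          WeightedDistanceSpec(n))
                for n in (2, 10, 100)]
        assert vals[0] >= vals[1] >= vals[2] >= dmin - 1e-12

    def test_numerically_stable_over_three_decades(self):
        """n=100 with distances 1..1000 A: finite, matches a naive oracle."""
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [30.0, 0, 0],
                           [1000.0, 0, 0]])
        ia, ib = np.array([0]), np.array([1, 2, 3])
        got = nb.weighted_mean_distance(coords, ia, ib,
                                        WeightedDistanceSpec(100))
        naive = (np.mean([1.0 ** -100, 30.0 ** -100, 1000.0 ** -100])
                 ** (-1 / 100))
        assert np.isfinite(got)
        assert got == pytest.approx(naive, rel=1e-6)
        # sub-Angstrom minimum overflows the naive sum but not the factored one
        coords[1, 0] = 0.05
        got = nb.weighted_mean_distance(coords, ia, ib,
                                        WeightedDistanceSpec(100))
        assert np.isfinite(got) and got >= 0.05

    def test_coincident_atoms_raise(self):
        coords = np.zeros((2, 3))
        with pytest.raises(nb.SingularDistanceError):
            nb.weighted_mean_distance(coords, [0], [1])

    def test_invalid_exponent_rejected(self):
        for n in (0, 3, -2):
            with pytest.raises(ValueError):
                WeightedDistanceSpec(n)


class TestTailSeries:
    def test_stride_row_count(self, scenario):
        traj, _, nuc = scenario
        series = nb.tail_configuration_series(traj, nuc, "H3_3p", stride=5)
        assert len(series) == traj.n_frames // 5
        assert list(series.columns) == ["frame", "time_ps", "delta_ldna",
                                        "delta_dyad", "nc_inner", "nc_outer",
                                        "tail_rg"]

    def test_mode_switch_visible_in_series(self, scenario):
        traj, truth, nuc = scenario
        series = nb.tail_configuration_series(traj, nuc, "H3_3p", stride=1)
        modes = np.array(truth.tail_modes["H3_3p"])
        bridged = series[modes == "bridge"]
        detached = series[modes == "detached"]
        assert (bridged["nc_outer"] > 0).all()
        assert (detached["nc_outer"] == 0).all()
        assert (detached["delta_ldna"] >= 10.0).all()

    def test_unknown_tail_raises(self, scenario):
        traj, _, nuc = scenario
        with pytest.raises(nb.SelectionError):
            nb.tail_configuration_series(traj, nuc, "H99_3p")


class TestResidueProfile:
    def test_default_h3_groups_resolve(self, scenario):
        traj, _, nuc = scenario
        prof = nb.residue_distance_profile(traj, nuc, "H3_3p", "outer",
                                           stride=50)
        labels = set(prof["residue"])
        expected = {r for group in nb.H3_RESIDUE_GROUPS.values() for r in group}
        assert labels == expected

    def test_wrong_residue_letter_raises(self, scenario):
        traj, _, nuc = scenario
        with pytest.raises(nb.SelectionError):
            nb.residue_distance_profile(
                traj, nuc, "H3_3p", "outer",
                residues={"tip": ("Q2",)}, stride=100)

    def test_single_bead_at_known_distance(self, ideal, nuc):
        """A bead placed 3 A from the nearest gyre atom reads back as
        delta_min in [3, 3*(N_gyre)^(1/100)]."""
        structure, _ = ideal
        coords = structure.coordinates.copy()
        gyre = nuc.gyre_atoms("outer")
        atom = nuc.residue_atoms(nuc.annotation.tail("H3_3p").chain_id, 2)
        target = coords[gyre[0]]
        away = target - coords[gyre].mean(axis=0)
        coords[atom] = target + 3.0 * away / np.linalg.norm(away)
        got = nb.weighted_mean_distance(coords, atom, gyre,
                                        WeightedDistanceSpec(100))
        assert 3.0 - 1e-9 <= got <= 3.0 * gyre.size ** 0.01 + 1e-9

    def test_delta_min_below_delta10(self, scenario):
        traj, _, nuc = scenario
        tail = nuc.tail_atoms("H3_3p")
        gyre = nuc.gyre_atoms("outer")
        for f in range(0, traj.n_frames, 40):
            d10 = nb.weighted_mean_distance(traj.coords[f], tail, gyre,
                                            WeightedDistanceSpec(10))
            d100 = nb.weighted_mean_distance(traj.coords[f], tail, gyre,
                                             WeightedDistanceSpec(100))
            assert d100 <= d10 + 1e-12


class TestClusterMedianHeatmap:
    @staticmethod
    def _profile(values_by_frame):
        rows = [(f, f * 1.0, "R2", "tip", "outer", v)
                for f, v in enumerate(values_by_frame)]
        return pd.DataFrame(rows, columns=["frame", "time_ps", "residue",
                                           "group", "gyre", "delta_min"])

    def test_single_cluster_constant(self):
        prof = self._profile([7.0] * 6)
        mat = nb.cluster_median_heatmap(prof, np.ones(6, dtype=int))
        assert mat.loc["R2", 1] == pytest.approx(7.0)

    def test_two_disjoint_clusters(self):
        prof = self._profile([3.0] * 4 + [11.0] * 4)
        assign = np.array([1] * 4 + [2] * 4)
        mat = nb.cluster_median_heatmap(prof, assign)
        assert mat.loc["R2", 1] == pytest.approx(3.0)
        assert mat.loc["R2", 2] == pytest.approx(11.0)

    def test_matches_sort_based_median_oracle(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(1, 40, 31)
        assign = rng.integers(1, 4, 31)
        mat = nb.cluster_median_heatmap(self._profile(vals), assign)
        for c in (1, 2, 3):
            sorted_vals = np.sort(vals[assign == c])
            k = sorted_vals.size
            oracle = (sorted_vals[k // 2] if k % 2
                      else 0.5 * (sorted_vals[k // 2 - 1] + sorted_vals[k // 2]))
            assert mat.loc["R2", c] == pytest.approx(oracle)

    def test_empty_cluster_flagged_missing(self):
        prof = self._profile([1.0, 2.0])   # frames 0 and 1 only
        assign = np.array([1, 1, 2])       # cluster 2 exists but unsampled
        mat = nb.cluster_median_heatmap(prof, assign)
        assert np.isnan(mat.loc["R2", 2])
        assert mat.loc["R2", 1] == pytest.approx(1.5)
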