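"""Structural analysis: RMSD, greedy clustering, contacts, hydropathy."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bemd import (
    DistanceMetricSpec, contact_difference, contact_matrix, daura_cluster,
    hydropathy_profile, make_cluster_fixture, population_errors,
    populations_at_centers, rmsd, rmsd_distribution, select_low_free_energy,
)
from bemd.analysis import pairwise_rmsd_matrix


def _metric(n, weights=None):
    return DistanceMetricSpec(subset=np.arange(n), weights=weights)


class TestRmsd:
    def test_identical_conformations_zero(self):
        c = np.random.default_rng(0).normal(size=(6, 3))
        assert rmsd(c, c, _metric(6)) == pytest.approx(0.0, abs=1e-12)

    def test_rigidly_rotated_copy_zero(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=(8, 3))
        rot = Rotation.from_rotvec([0.4, -0.9, 1.3]).as_matrix()
        c2 = c @ rot.T + np.array([2.0, 0.5, -1.0])
        assert rmsd(c, c2, _metric(8)) == pytest.approx(0.0, abs=1e-8)

    def test_matches_brute_force_rotation_search(self):
        """Weighted superposition RMSD vs a dense rotation-grid minimisation."""
        rng = np.random.default_rng(2)
        a = rng.normal(size=(4, 3))
        b = rng.normal(size=(4, 3))
        w = np.array([1.0, 2.0, 1.0, 3.0])
        metric = _metric(4, weights=w)
        got = rmsd(a, b, metric)
        # brute force: random rotations + local refinement by annealing the grid
        ac = a - np.average(a, axis=0, weights=w)
        bc = b - np.average(b, axis=0, weights=w)

        def wrms(rotm):
            d = ac - bc @ rotm.T
            return np.sqrt(np.sum(w[:, None] * d * d) / w.sum())

        best = np.inf
        best_rv = np.zeros(3)
        for rv in rng.uniform(-np.pi, np.pi, size=(4000, 3)):
            val = wrms(Rotation.from_rotvec(rv).as_matrix())
            if val < best:
                best, best_rv = val, rv
        scale = 0.3
        for _ in range(60):
            improved = False
            for rv in best_rv + rng.normal(scale=scale, size=(300, 3)):
                val = wrms(Rotation.from_rotvec(rv).as_matrix())
                if val < best:
                    best, best_rv, improved = val, rv, True
            if not improved:
                scale *= 0.5
        assert got == pytest.approx(best, abs=1e-6)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(3)
        metric = _metric(5)
        for _ in range(10):
            a, b, c = rng.normal(size=(3, 5, 3))
            dab, dba = rmsd(a, b, metric), rmsd(b, a, metric)
            assert dab == pytest.approx(dba, abs=1e-8)
            assert rmsd(a, c, metric) <= dab + rmsd(b, c, metric) + 1e-8

    def test_subset_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsd(np.zeros((4, 3)), np.zeros((5, 3)), _metric(5))


def _brute_force_daura(dmat, cutoff):
    """Independent greedy reimplementation used as the clustering oracle."""
    n = dmat.shape[0]
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        best_center, best_count = None, -1
        for i in sorted(unassigned):
            count = sum(1 for j in unassigned if j != i and dmat[i, j] < cutoff)
            if count > best_count:
                best_center, best_count = i, count
        members = sorted(j for j in unassigned
                         if j == best_center or dmat[best_center, j] < cutoff)
        clusters.append((best_center, members))
        unassigned -= set(members)
    return clusters


class TestDauraCluster:
    def test_all_far_apart_gives_singletons(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(5, 6, 3)) * 5.0
        res = daura_cluster(coords, None, _metric(6), cutoff=1e-6)
        assert len(res.centers) == 5
        assert all(len(m) == 1 for m in res.members)

    def test_all_close_gives_one_cluster(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(6, 3))
        coords = base[None] + 1e-4 * rng.normal(size=(7, 6, 3))
        res = daura_cluster(coords, None, _metric(6), cutoff=1.0)
        assert len(res.centers) == 1
        assert res.populations[0] == pytest.approx(1.0)

    def test_planted_fixture_recovered_exactly(self):
        fix = make_cluster_fixture(n_clusters=3, n_per_cluster=10, spread=0.1,
                                   separation=1.0, seed=6)
        res = daura_cluster(fix.conformations, None, fix.metric, cutoff=fix.cutoff)
        assert len(res.centers) == 3
        labels = res.labels(len(fix.planted_labels))
        # same partition as planted (up to cluster relabelling)
        for k in range(3):
            members = labels[fix.planted_labels == k]
            assert len(set(members.tolist())) == 1

    def test_matches_brute_force_on_random_ensembles(self):
        """Exact agreement with an independent implementation, 200 snapshots."""
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(200, 5, 3))
        metric = _metric(5)
        dmat = pairwise_rmsd_matrix(coords, metric)
        cutoff = float(np.percentile(dmat[dmat > 0], 10))
        res = daura_cluster(coords, None, metric, cutoff=cutoff, rmsd_matrix=dmat)
        oracle = _brute_force_daura(dmat, cutoff)
        assert len(res.centers) == len(oracle)
        for (c_pkg, m_pkg), (c_orc, m_orc) in zip(
            zip(res.centers, res.members), oracle
        ):
            assert c_pkg == c_orc
            assert sorted(m_pkg.tolist()) == m_orc

    def test_populations_sum_to_one_with_weights(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(30, 4, 3))
        w = rng.uniform(0.1, 1.0, size=30)
        res = daura_cluster(coords, w, _metric(4), cutoff=0.8)
        assert res.populations.sum() == pytest.approx(1.0, abs=1e-10)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            daura_cluster(np.zeros((0, 3, 3)), None, _metric(3), cutoff=1.0)


class TestSelectLowFreeEnergy:
    def _binset(self, fs, occupants):
        from bemd.reweight import BinRecord, BinSet, CVGridSpec

        bins = []
        row = 0
        for f, n in zip(fs, occupants):
            rows = list(range(row, row + n))
            row += n
            bins.append(BinRecord(index=(len(bins),), snapshots={0: rows},
                                  occupancy=n, free_energy=f, weight=1.0 / len(fs)))
        spec = CVGridSpec(cv_names=["x"], widths=[1.0], origin=[0.0])
        return BinSet(grid_spec=spec, bins=bins, overflow=BinRecord(("o",), {}),
                      ensembles=[0])

    def test_infinite_threshold_keeps_everything(self):
        bs = self._binset([0.0, 5.0, 50.0], [2, 2, 2])
        assert len(select_low_free_energy(bs, np.inf)) == 6

    def test_zero_threshold_keeps_only_minimum(self):
        bs = self._binset([0.0, 5.0, 50.0], [2, 3, 4])
        assert len(select_low_free_energy(bs, 0.0)) == 2

    def test_six_kt_boundary(self):
        from bemd.constants import KB

        kT = KB * 300.0
        bs = self._binset([0.0, 7.0 * kT], [3, 3])
        rows = select_low_free_energy(bs, 6.0)
        assert len(rows) == 3  # the 7 kT bin is excluded at the default 6 kT


class TestContactMatrix:
    def test_exact_counts_at_cutoff(self):
        # two groups; one pair at 2.9 A (contact), one at 3.1 A (no contact)
        coords = np.array([[[0, 0, 0], [0.29, 0, 0], [1.0, 0, 0], [1.31, 0, 0]]])
        groups = {"A": [0], "B": [1], "C": [2], "D": [3]}
        cm = contact_matrix(coords, None, groups, cutoff=3.0)
        assert cm[("A", "B")] == pytest.approx(1.0)
        assert cm[("C", "D")] == pytest.approx(0.0)

    def test_cutoff_sensitivity_band(self):
        """±0.5 A changes only entries whose pair distances lie inside the band."""
        coords = np.array([[[0, 0, 0], [0.27, 0, 0], [1.0, 0, 0], [1.45, 0, 0],
                            [3.0, 0, 0], [3.06, 0, 0]]])
        groups = {f"G{i}": [i] for i in range(6)}
        base = contact_matrix(coords, None, groups, cutoff=3.0)
        lo = contact_matrix(coords, None, groups, cutoff=2.5)
        hi = contact_matrix(coords, None, groups, cutoff=3.5)
        # pair at 2.7 A: inside [2.5, 3.5) band -> flips at the lower cutoff
        assert base[("G0", "G1")] == 1.0 and lo[("G0", "G1")] == 0.0
        # pair at 4.5 A: outside the band -> unchanged everywhere
        assert base[("G2", "G3")] == lo[("G2", "G3")] == hi[("G2", "G3")] == 0.0
        # pair at 0.6 A: outside the band -> unchanged everywhere
        assert base[("G4", "G5")] == lo[("G4", "G5")] == hi[("G4", "G5")] == 1.0

    def test_weighted_average_over_frames(self):
        c1 = np.array([[0, 0, 0], [0.2, 0, 0]])
        c2 = np.array([[0, 0, 0], [0.9, 0, 0]])
        coords = np.stack([c1, c2])
        cm = contact_matrix(coords, np.array([0.75, 0.25]), {"A": [0], "B": [1]},
                            cutoff=3.0)
        assert cm[("A", "B")] == pytest.approx(0.75)

    def test_symmetry_and_empty_group_warning(self):
        rng = np.random.default_rng(9)
        coords = rng.uniform(0, 0.5, size=(3, 6, 3))
        groups = {"A": [0, 1], "B": [2, 3, 4], "C": [5]}
        cm = contact_matrix(coords, None, groups, cutoff=3.0)
        np.testing.assert_allclose(cm.counts, cm.counts.T, atol=1e-12)
        with pytest.warns(UserWarning, match="no proton"):
            contact_matrix(coords, None, {"A": [0], "E": []}, cutoff=3.0)


class TestContactDifference:
    def _mat(self, labels, counts):
        from bemd.analysis import ContactMatrix

        return ContactMatrix(labels=labels, counts=np.asarray(counts, dtype=float),
                             cutoff=3.0)

    def test_identical_matrices_give_zero(self):
        m = self._mat(["R1", "R2"], [[1.0, 0.5], [0.5, 2.0]])
        d = contact_difference(m, m)
        np.testing.assert_array_equal(d.counts, 0.0)

    def test_zero_apo_returns_holo(self):
        holo = self._mat(["R1", "R2"], [[1.0, 0.5], [0.5, 2.0]])
        apo = self._mat(["R1", "R2"], [[0.0, 0.0], [0.0, 0.0]])
        d = contact_difference(holo, apo)
        np.testing.assert_array_equal(d.counts, holo.counts)

    def test_antisymmetry_on_shared_block(self):
        a = self._mat(["R1", "R2"], [[1.0, 0.2], [0.2, 0.7]])
        b = self._mat(["R1", "R2"], [[0.4, 0.9], [0.9, 0.1]])
        d1 = contact_difference(a, b)
        d2 = contact_difference(b, a)
        np.testing.assert_allclose(d1.counts, -d2.counts, atol=1e-12)

    def test_ligand_rows_allowed_only_in_holo(self):
        holo = self._mat(["R1", "LIG"], [[1.0, 0.5], [0.5, 0.0]])
        apo = self._mat(["R1"], [[0.3]])
        d = contact_difference(holo, apo)
        assert d[("R1", "R1")] == pytest.approx(0.7)
        assert d[("R1", "LIG")] == pytest.approx(0.5)  # holo-only block untouched
        with pytest.raises(ValueError):
            contact_difference(apo, holo)


class TestRmsdDistribution:
    def test_reference_in_ensemble_is_point_mass_at_zero(self):
        c = np.random.default_rng(0).normal(size=(1, 5, 3))
        hist = rmsd_distribution(c, c[0], None, _metric(5))
        assert hist.fraction_below == pytest.approx(1.0)
        assert hist.rmsd_values[0] == pytest.approx(0.0, abs=1e-5)

    def test_infinite_threshold_fraction_is_one(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=(10, 5, 3))
        hist = rmsd_distribution(c, c[0], None, _metric(5), threshold=np.inf)
        assert hist.fraction_below == pytest.approx(1.0)

    def test_histogram_counts_match_hand_tally(self):
        """Ten conformations at constructed RMSDs tally into the right bins."""
        base = np.zeros((4, 3))
        base[1, 0] = base[2, 1] = base[3, 2] = 1.0
        targets_nm = np.array([0.0, 0.01, 0.03, 0.06, 0.06, 0.11, 0.14, 0.14, 0.14, 0.21])
        coords = []
        for t in targets_nm:
            c = base.copy()
            # displace all atoms along a direction orthogonal to their spread:
            # centred displacement d on every atom gives RMSD = |d|... not after
            # fitting; instead stretch atom 1 away from the centroid
            c[1, 0] += 2 * t
            coords.append(c)
        coords = np.asarray(coords)
        metric = _metric(4)
        vals = np.array([rmsd(c, coords[0], metric) for c in coords]) * 10.0
        hist = rmsd_distribution(coords, coords[0], None, metric, bin_width=0.5)
        tally, _ = np.histogram(vals, bins=hist.bin_edges)
        dens = tally / tally.sum() / 0.5
        np.testing.assert_allclose(hist.densities, dens, atol=1e-12)


class TestHydropathy:
    def test_triple_isoleucine(self):
        prof = hydropathy_profile("III", window=3)
        assert prof.scores[0] == pytest.approx(4.5)

    def test_triple_tyrosine_scores_as_phenylalanine(self):
        prof = hydropathy_profile("YYY", window=3)
        assert prof.scores[0] == pytest.approx(2.8)
        unmodified = hydropathy_profile("YYY", window=3, tyrosine_as_phenylalanine=False)
        assert unmodified.scores[0] == pytest.approx(-1.3)

    def test_profile_length(self):
        seq = "A" * 84
        prof = hydropathy_profile(seq, window=3)
        assert len(prof.scores) == 82

    def test_invalid_residue_reported_with_position(self):
        with pytest.raises(ValueError, match="position 3"):
            hydropathy_profile("ILX", window=3)

    def test_window_mean_hand_check(self):
        prof = hydropathy_profile("IVL", window=3)
        assert prof.scores[0] == pytest.approx((4.5 + 4.2 + 3.8) / 3)


class TestPopulationErrors:
    def test_identical_runs_zero_error(self):
        mean, se = population_errors([0.3, 0.7], [0.3, 0.7])
        np.testing.assert_allclose(se, 0.0)

    def test_two_sample_standard_error(self):
        mean, se = population_errors([0.08], [0.12])
        assert mean[0] == pytest.approx(0.10)
        assert se[0] == pytest.approx(0.02)

    def test_order_invariance(self):
        m1, s1 = population_errors([0.2, 0.8], [0.4, 0.6])
        m2, s2 = population_errors([0.4, 0.6], [0.2, 0.8])
        np.testing.assert_allclose(m1, m2)
        np.testing.assert_allclose(s1, s2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            population_errors([0.5], [0.3, 0.2])


def test_populations_at_fixed_centers_respects_center_order():
    fix = make_cluster_fixture(n_clusters=2, n_per_cluster=5, spread=0.05,
                               separation=1.0, seed=10)
    res = daura_cluster(fix.conformations, None, fix.metric, cutoff=fix.cutoff)
    centers = fix.conformations[res.centers]
    pops = populations_at_centers(fix.conformations, None, centers, fix.metric,
                                  cutoff=fix.cutoff)
    np.testing.assert_allclose(np.sort(pops), [0.5, 0.5], atol=1e-12)


def test_cluster_fixture_inequalities_and_seed_determinism():
    fix1 = make_cluster_fixture(3, 4, spread=0.08, separation=0.9, seed=3)
    fix2 = make_cluster_fixture(3, 4, spread=0.08, separation=0.9, seed=3)
    np.testing.assert_array_equal(fix1.conformations, fix2.conformations)
    with pytest.raises(ValueError, match="separation"):
        make_cluster_fixture(3, 4, spread=0.3, separation=1.0, seed=0)
    # spread=0 duplicates the center exactly
    fix0 = make_cluster_fixture(2, 3, spread=0.0, separation=1.0, seed=1)
    d = pairwise_rmsd_matrix(fix0.conformations[:3], fix0.metric)
    assert np.max(d) < 1e-10
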