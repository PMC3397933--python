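"""FES construction, hypercube binning, WHAM closed forms, ensemble averages."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from bemd import (
    CVGridSpec, HillsLedger, bin_snapshots, compare_profiles, deposit,
    fes_from_hills, fes_from_neutral_histogram, neutral_replica_average,
    wham_bin_free_energies, weighted_average,
)
from bemd.constants import KB

KT = KB * 300.0


class TestFesFromHills:
    def test_single_hill_profile(self):
        """F = -(hill) shifted so the far field (no bias) sits at zero."""
        ledger = HillsLedger("x", pace=2.0)
        deposit(ledger, 0.0, 2.0, height=1.0, width=0.1)
        grid = np.linspace(-2.0, 2.0, 401)
        prof = fes_from_hills(ledger, grid, window=(2.0, 2.0 + 1e-9))
        assert prof.free_energy.min() == pytest.approx(0.0)
        # far from the hill the bias vanishes -> F = +height after the shift
        assert prof.interp(-2.0) == pytest.approx(1.0, abs=1e-6)
        assert prof.interp(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_identical_ledgers_identical_profiles(self):
        grids = np.linspace(-1.5, 1.5, 101)
        ledgers = []
        for _ in range(2):
            lg = HillsLedger("x", pace=2.0)
            for k, s in enumerate((0.3, -0.7, 0.1, 0.9)):
                deposit(lg, s, 2.0 * (k + 1), 0.2, 0.07)
            ledgers.append(lg)
        p1 = fes_from_hills(ledgers[0], grids, (2.0, 8.0))
        p2 = fes_from_hills(ledgers[1], grids, (2.0, 8.0))
        np.testing.assert_array_equal(p1.free_energy, p2.free_energy)

    def test_empty_window_rejected(self):
        lg = HillsLedger("x", pace=2.0)
        deposit(lg, 0.0, 2.0, 0.2, 0.07)
        with pytest.raises(ValueError, match="window"):
            fes_from_hills(lg, np.linspace(-1, 1, 11), (100.0, 200.0))


class TestBinSnapshots:
    def _colvar(self, xs, ens=0):
        return pd.DataFrame({"time": np.arange(len(xs), dtype=float),
                             "x": xs, "assignment": ens})

    def test_single_snapshot_single_bin(self):
        spec = CVGridSpec(cv_names=["x"], widths=[0.2], origin=[0.0])
        bs = bin_snapshots(self._colvar([0.35]), spec, min_occupancy=1)
        assert len(bs.bins) == 1
        assert bs.bins[0].index == (1,)
        assert bs.bins[0].occupancy == 1

    def test_edge_value_goes_to_upper_bin(self):
        spec = CVGridSpec(cv_names=["x"], widths=[0.2], origin=[0.0])
        bs = bin_snapshots(self._colvar([0.2]), spec, min_occupancy=1)
        assert bs.bins[0].index == (1,)  # [0.2, 0.4), lower-closed

    def test_uniform_occupancy_counting(self):
        """100 snapshots uniform over 10 bins: all retained at min_occupancy 5."""
        rng = np.random.default_rng(8)
        xs = rng.uniform(0.0, 1.0, size=100)
        spec = CVGridSpec(cv_names=["x"], widths=[0.1], origin=[0.0])
        bs = bin_snapshots(self._colvar(xs), spec, min_occupancy=5)
        # direct counting oracle
        counts = np.histogram(xs, bins=np.linspace(0, 1, 11))[0]
        assert sum(b.occupancy for b in bs.bins) == 100
        assert len(bs.retained) == int(np.sum(counts >= 5))

    def test_out_of_bounds_goes_to_overflow(self):
        spec = CVGridSpec(cv_names=["x"], widths=[0.2], origin=[0.0],
                          bounds=[(0.0, 1.0)])
        with pytest.warns(UserWarning, match="outside"):
            bs = bin_snapshots(self._colvar([0.5, 1.7]), spec, min_occupancy=1)
        assert bs.overflow.occupancy == 1
        assert sum(b.occupancy for b in bs.bins) == 1


class TestWham:
    def _binset(self, xs, ens, spec=None):
        df = pd.DataFrame({"time": np.arange(len(xs), dtype=float), "x": xs,
                           "assignment": ens})
        spec = spec or CVGridSpec(cv_names=["x"], widths=[1.0], origin=[0.0])
        return df, bin_snapshots(df, spec, min_occupancy=1)

    def test_zero_bias_degenerates_to_raw_histogram(self):
        rng = np.random.default_rng(3)
        xs = rng.uniform(0, 4, size=200)
        df, bs = self._binset(xs, 0)
        zero = {0: lambda s: np.zeros_like(np.asarray(s, dtype=float))}
        bs = wham_bin_free_energies(bs, zero, colvar=df, cv_of_ensemble={0: "x"})
        counts = np.array([b.occupancy for b in bs.retained], dtype=float)
        expect = -KT * np.log(counts / counts.sum())
        expect -= expect.min()
        got = np.array([b.free_energy for b in bs.retained])
        np.testing.assert_allclose(got, expect, atol=1e-8)

    def test_two_bin_two_replica_matches_algebraic_solution(self):
        """Iterate agrees with the self-consistency root solved independently."""
        # ensemble 0: 30 snapshots in bin 0, 10 in bin 1; ensemble 1: 5 and 25;
        # ensemble biases differ across bins -> nontrivial fixed point
        xs = ([0.5] * 30 + [1.5] * 10) + ([0.5] * 5 + [1.5] * 25)
        ens = [0] * 40 + [1] * 30
        df, bs = self._binset(xs, ens)
        v0 = lambda s: np.where(np.asarray(s) < 1.0, 0.0, 2.0)
        v1 = lambda s: np.where(np.asarray(s) < 1.0, 3.0, 0.0)
        bs = wham_bin_free_energies(bs, {0: v0, 1: v1}, colvar=df,
                                    cv_of_ensemble={0: "x", 1: "x"}, tol=1e-12)
        p_pkg = np.array([b.weight for b in bs.retained])

        # independent oracle: reduce the WHAM equations to one unknown r = p1/p0
        beta = 1.0 / KT
        n = np.array([[35.0, 5.0], [35.0, 25.0]])  # counts[bin, ens] -- see below
        n = np.array([[30.0 + 5.0, 10.0 + 25.0]])
        counts_bin = np.array([35.0, 35.0])
        N_r = np.array([40.0, 30.0])
        V = np.array([[0.0, 3.0], [2.0, 0.0]])  # V[bin, ens]

        def residual(r):
            p = np.array([1.0, r]) / (1.0 + r)
            zr = (p[:, None] * np.exp(-beta * V)).sum(axis=0)
            denom = (N_r[None, :] / zr[None, :] * np.exp(-beta * V)).sum(axis=1)
            p_new = counts_bin / denom
            p_new = p_new / p_new.sum()
            return p_new[1] / p_new[0] - r

        r_star = brentq(residual, 1e-6, 1e6, xtol=1e-14)
        p_oracle = np.array([1.0, r_star]) / (1.0 + r_star)
        np.testing.assert_allclose(p_pkg, p_oracle, atol=1e-8)

    def test_gauge_invariance_under_constant_bias_shift(self):
        rng = np.random.default_rng(5)
        xs = np.concatenate([rng.uniform(0, 3, 150), rng.uniform(1, 4, 150)])
        ens = [0] * 150 + [1] * 150
        df, bs1 = self._binset(xs, ens)
        _, bs2 = self._binset(xs, ens)
        v0 = lambda s: 0.5 * np.asarray(s, dtype=float)
        v1 = lambda s: -0.3 * np.asarray(s, dtype=float)
        shift = 7.0
        bs1 = wham_bin_free_energies(bs1, {0: v0, 1: v1}, colvar=df,
                                     cv_of_ensemble={0: "x", 1: "x"}, tol=1e-10)
        bs2 = wham_bin_free_energies(
            bs2, {0: lambda s: v0(s) + shift, 1: lambda s: v1(s) + shift},
            colvar=df, cv_of_ensemble={0: "x", 1: "x"}, tol=1e-10)
        f1 = np.array([b.free_energy for b in bs1.retained])
        f2 = np.array([b.free_energy for b in bs2.retained])
        np.testing.assert_allclose(f1, f2, atol=1e-8)

    def test_empty_bin_set_rejected(self):
        df, bs = self._binset([0.5] * 3, 0)
        bs.bins[0].excluded = True
        with pytest.raises(ValueError, match="retained"):
            wham_bin_free_energies(bs, {0: lambda s: 0.0})


class TestAverages:
    def _wham_binset(self, xs, obs_spec=None):
        df = pd.DataFrame({"time": np.arange(len(xs), dtype=float), "x": xs,
                           "assignment": 0})
        spec = CVGridSpec(cv_names=["x"], widths=[1.0], origin=[0.0])
        bs = bin_snapshots(df, spec, min_occupancy=1)
        zero = {0: lambda s: np.zeros_like(np.asarray(s, dtype=float))}
        return df, wham_bin_free_energies(bs, zero, colvar=df, cv_of_ensemble={0: "x"})

    def test_constant_observable_gives_one(self):
        df, bs = self._wham_binset([0.5, 1.5, 2.5, 0.7, 1.1])
        assert weighted_average(bs, np.ones(5)) == pytest.approx(1.0, abs=1e-12)

    def test_single_bin_reduces_to_plain_mean(self):
        df, bs = self._wham_binset([0.1, 0.5, 0.9])
        obs = np.array([2.0, 4.0, 9.0])
        assert weighted_average(bs, obs) == pytest.approx(np.mean(obs))

    def test_missing_observables_dropped_with_warning(self):
        df, bs = self._wham_binset([0.1, 0.5, 0.9])
        obs = np.array([2.0, np.nan, 4.0])
        with pytest.warns(UserWarning, match="dropped"):
            assert weighted_average(bs, obs) == pytest.approx(3.0)

    def test_neutral_average_basics(self):
        assert neutral_replica_average([3.0, 3.0, 3.0]) == 3.0
        vals = [1.0, 5.0, 2.0, 8.0]
        assert neutral_replica_average(vals) == neutral_replica_average(vals[::-1])
        with pytest.raises(ValueError):
            neutral_replica_average([])


class TestNeutralHistogramFes:
    def test_uniform_samples_give_flat_profile(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.0, 1.0, size=200_000)
        prof = fes_from_neutral_histogram(vals, "x", np.linspace(0, 1, 11))
        assert np.nanmax(prof.free_energy) < 0.05 * KT

    def test_empty_cells_are_nan_not_zero(self):
        vals = np.array([0.05, 0.06, 0.07, 0.95])
        prof = fes_from_neutral_histogram(vals, "x", np.linspace(0, 1, 11))
        assert np.isnan(prof.free_energy[5])
        assert np.isfinite(prof.free_energy[0])

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            fes_from_neutral_histogram(np.array([5.0]), "x", np.linspace(0, 1, 11))


def test_compare_profiles_restricts_to_low_free_energy_region():
    from bemd.reweight import FESProfile1D

    g = np.linspace(0, 1, 11)
    p1 = FESProfile1D("x", g, np.abs(g - 0.5) * 10)
    p2 = FESProfile1D("x", g, np.abs(g - 0.5) * 10 + np.where(g > 0.9, 5.0, 0.1))
    rms, mx = compare_profiles(p1, p2, max_f=2.0)
    assert mx <= 0.1 + 1e-9  # the +5 outlier lies outside the compared region
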