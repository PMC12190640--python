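"""Simulator correctness: generator construction, Gillespie sampling,
frame integration, emission, photobleaching, and dataset assembly."""

import numpy as np
import pytest
from scipy import stats as sps

import ribofret as rf
from ribofret.simulate import two_state_rates


class TestBuildGenerator:
    def test_symmetric_two_state(self):
        rm = rf.build_generator((0.5, 0.5), exchange_timescale=10.0)
        assert rm.q[0, 1] == pytest.approx(rm.q[1, 0])

    def test_stationary_matches_occupancies(self):
        occ = np.array([0.597, 0.217, 0.186])
        rm = rf.build_generator(occ, exchange_timescale=5.0)
        # direct oracle: pi Q = 0 for the requested pi
        np.testing.assert_allclose(occ @ rm.q, 0.0, atol=1e-9)
        np.testing.assert_allclose(rm.stationary_distribution(), occ, atol=1e-9)

    def test_only_adjacent_transitions(self):
        rm = rf.build_generator((0.3, 0.3, 0.4), exchange_timescale=5.0)
        assert rm.q[0, 2] == 0.0 and rm.q[2, 0] == 0.0

    def test_exchange_timescale_sets_transition_frequency(self):
        occ = np.array([0.2, 0.5, 0.3])
        tau = 4.0
        rm = rf.build_generator(occ, tau)
        freq = -(occ * np.diag(rm.q)).sum()
        assert freq == pytest.approx(1.0 / tau, rel=1e-9)

    def test_two_state_explicit_rates_stationary(self):
        rm = two_state_rates(k_fold=0.097, k_unfold=0.167)
        pi = rm.stationary_distribution()
        # closed form k_f / (k_f + k_u)
        assert pi[1] == pytest.approx(0.097 / (0.097 + 0.167), abs=1e-12)

    @pytest.mark.parametrize("occ", [(0.5, 0.6), (0.0, 1.0), (0.3, -0.1, 0.8)])
    def test_invalid_occupancies_rejected(self, occ):
        with pytest.raises(ValueError):
            rf.build_generator(occ, 5.0)


class TestStatePath:
    def test_zero_rates_single_dwell(self):
        rm = rf.RateMatrix(np.zeros((2, 2)))
        cps, states = rf.simulate_state_path(rm, 50.0, rng=1, initial_state=1)
        assert len(states) == 1 and states[0] == 1

    def test_mean_dwell_matches_rate(self):
        rm = two_state_rates(0.1, 0.1)
        cps, states = rf.simulate_state_path(rm, 1e4, rng=2)
        dwells = np.diff(cps)
        se = dwells.std() / np.sqrt(len(dwells))
        assert abs(dwells.mean() - 10.0) < 3 * se

    def test_same_seed_identical_paths(self):
        rm = two_state_rates(0.2, 0.3)
        a = rf.simulate_state_path(rm, 100.0, rng=7)
        b = rf.simulate_state_path(rm, 100.0, rng=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_dwells_exponential_ks(self):
        """Pooled per-state dwells follow Exp(exit rate) (KS at alpha=0.01)."""
        k12, k21 = 0.5, 0.8
        rm = two_state_rates(k12, k21)
        rng = np.random.default_rng(3)
        dwells = {0: [], 1: []}
        t_total = 0.0
        while sum(len(v) for v in dwells.values()) < 10_000:
            cps, states = rf.simulate_state_path(rm, 2000.0, rng)
            for s, d in zip(states[:-1], np.diff(cps)):
                dwells[s].append(d)
            t_total += 2000.0
        for s, rate in [(0, k12), (1, k21)]:
            d = np.asarray(dwells[s])
            p = sps.kstest(d, "expon", args=(0, 1.0 / rate)).pvalue
            assert p > 0.01, f"state {s} dwells not exponential (p={p:.2g})"

    def test_stationary_occupancy_of_many_paths(self):
        occ = np.array([0.597, 0.217, 0.186])
        rm = rf.build_generator(occ, exchange_timescale=5.0)
        rng = np.random.default_rng(4)
        time_in = np.zeros(3)
        for _ in range(500):
            cps, states = rf.simulate_state_path(rm, 100.0, rng)
            bounds = np.append(cps, 100.0)
            np.add.at(time_in, states, np.diff(bounds))
        frac = time_in / time_in.sum()
        # ~2000 decorrelated dwell-scale samples per state: atol 0.02 is ~4 SE
        np.testing.assert_allclose(frac, occ, atol=0.02)


class TestDiscretize:
    def test_boundary_transition_keeps_frames_pure(self):
        occ = rf.discretize_path(np.array([0.0, 0.2]), np.array([0, 1]), 2, 0.4, 0.1)
        np.testing.assert_allclose(occ, [[1, 0], [1, 0], [0, 1], [0, 1]])

    def test_midframe_transition_splits_half_half(self):
        occ = rf.discretize_path(np.array([0.0, 0.25]), np.array([0, 1]), 2, 0.5, 0.1)
        np.testing.assert_allclose(occ[2], [0.5, 0.5])

    def test_occupancy_conserves_mean_efret(self):
        """Occupancy-weighted E equals the time integral of the true E."""
        rm = rf.build_generator((0.4, 0.35, 0.25), 2.0)
        centers = np.array([0.2, 0.6, 0.8])
        rng = np.random.default_rng(5)
        for _ in range(10):
            cps, states = rf.simulate_state_path(rm, 50.0, rng)
            occ = rf.discretize_path(cps, states, 3, 50.0, 0.1)
            bounds = np.append(cps, 50.0)
            integral = np.sum(np.diff(bounds) * centers[states]) / 50.0
            frame_mean = (occ @ centers).mean()
            assert frame_mean == pytest.approx(integral, abs=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(6)
        cps, states = rf.simulate_state_path(two_state_rates(1.0, 1.0), 20.0, rng)
        occ = rf.discretize_path(cps, states, 2, 20.0, 0.1)
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(occ >= 0)


def noiseless_emission(centers=(0.2, 0.6, 0.8)):
    return rf.EmissionModel(
        state_centers=centers,
        state_sigma=(0.0,) * len(centers),
        total_intensity=1000.0,
        intensity_sigma=0.0,
    )


class TestEmit:
    def test_pure_state_noiseless(self):
        occ = np.zeros((5, 3))
        occ[:, 2] = 1.0
        tr = rf.emit_trace(occ, noiseless_emission(), rng=1)
        np.testing.assert_allclose(tr.acceptor, 800.0)
        np.testing.assert_allclose(tr.donor, 200.0)

    def test_mixture_frame_averages_centers(self):
        occ = np.array([[0.5, 0.5]])
        em = noiseless_emission(centers=(0.2, 0.6))
        tr = rf.emit_trace(occ, em, rng=1)
        e = tr.acceptor / (tr.acceptor + tr.donor)
        assert e[0] == pytest.approx(0.4, abs=1e-12)

    def test_noisy_mean_converges_to_center(self):
        occ = np.zeros((10_000, 2))
        occ[:, 1] = 1.0
        em = rf.EmissionModel((0.2, 0.8), (0.07, 0.07), 1000.0, 40.0)
        tr = rf.emit_trace(occ, em, rng=2)
        e = tr.acceptor / tr.total
        se = e.std() / 100.0
        assert abs(e.mean() - 0.8) < 3 * se + 0.01


class TestPhotobleach:
    def test_infinite_lifetimes_leave_trace_unchanged(self):
        occ = np.ones((50, 1))
        em = noiseless_emission(centers=(0.8,))
        tr = rf.emit_trace(occ, em, rng=1)
        out, td, ta = rf.apply_photobleach(tr, np.inf, np.inf, em, rng=1)
        np.testing.assert_array_equal(out.donor, tr.donor)
        assert not np.isfinite(td) and not np.isfinite(ta)

    def test_donor_bleach_kills_both_channels(self):
        occ = np.ones((200, 1))
        em = noiseless_emission(centers=(0.8,))
        tr = rf.emit_trace(occ, em, rng=1)
        rng = np.random.default_rng(3)
        out, td, ta = rf.apply_photobleach(tr, 5.0, np.inf, em, rng)
        b = int(td / 0.1)
        if b < 200:
            assert np.all(out.total[b:] == pytest.approx(0.0, abs=1e-9))

    def test_acceptor_bleach_moves_intensity_to_donor(self):
        occ = np.ones((200, 1))
        em = noiseless_emission(centers=(0.8,))
        tr = rf.emit_trace(occ, em, rng=1)
        rng = np.random.default_rng(4)
        out, td, ta = rf.apply_photobleach(tr, np.inf, 5.0, em, rng)
        b = int(ta / 0.1)
        if b < 200:
            np.testing.assert_allclose(out.acceptor[b:], 0.0, atol=1e-9)
            np.testing.assert_allclose(out.donor[b:], 1000.0, atol=1e-9)

    def test_bleach_times_exponential_mean(self):
        em = noiseless_emission(centers=(0.8,))
        occ = np.ones((2, 1))
        tr = rf.emit_trace(occ, em, rng=1)
        rng = np.random.default_rng(5)
        times = np.array(
            [rf.apply_photobleach(tr, 80.0, np.inf, em, rng)[1] for _ in range(2000)]
        )
        se = times.std() / np.sqrt(len(times))
        assert abs(times.mean() - 80.0) < 3 * se


class TestGenerateDataset:
    def test_static_fraction_one_gives_single_state_paths(self):
        fix = rf.ConditionFixture(
            name="all_static",
            emission=noiseless_emission(),
            occupancies=(0.4, 0.3, 0.3),
            static_fraction=1.0,
            static_state=2,
            donor_lifetime=np.inf,
            acceptor_lifetime=np.inf,
        )
        ts, gt = rf.generate_dataset(fix, 10, seed=1)
        assert all(m["static"] for m in gt.molecules)
        for tr in ts:
            np.testing.assert_allclose(tr.acceptor, 800.0, atol=1e-9)

    def test_pooled_true_occupancy_matches_fixture(self):
        fix = rf.get_fixture("noMg_occupancy")
        occ_target = np.array([0.597, 0.217, 0.186])
        ts, gt = rf.generate_dataset(fix, 574, seed=7)
        time_in = np.zeros(3)
        for m in gt.molecules:
            cps = np.array(m["change_points_s"])
            states = np.array(m["states"])
            bounds = np.append(cps, fix.duration)
            np.add.at(time_in, states, np.diff(bounds))
        frac = time_in / time_in.sum()
        # per-molecule time fractions have sd ~0.25 (correlated within a
        # trace); 3 SE over 574 molecules is ~0.032
        np.testing.assert_allclose(frac, occ_target, atol=0.035)

    def test_fixed_seed_byte_identical_output(self, tmp_path):
        fix = rf.get_fixture("mg2mM")
        for d in ("a", "b"):
            ts, gt = rf.generate_dataset(fix, 5, seed=11)
            rf.write_dataset(ts, tmp_path / d, ground_truth=gt.to_dict())
        for rel in ["manifest.json", "ground_truth.json", "traces/mol_0000.csv"]:
            assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()

    def test_unknown_fixture_name(self):
        with pytest.raises(KeyError, match="unknown fixture"):
            rf.get_fixture("nope")


class TestTitration:
    def test_zero_concentration_baseline(self):
        series = rf.generate_titration([0.0, 0.05, 0.1, 1.0], 1, seed=1)
        occ0 = series[0][1].manifest["occupancies"]
        assert occ0[2] == pytest.approx(0.186, abs=1e-12)

    def test_plateau_and_midpoint(self):
        assert rf.hill_fraction(1e3, 0.186, 0.596, 0.06) == pytest.approx(0.596, abs=1e-3)
        assert rf.hill_fraction(0.06, 0.186, 0.596, 0.06) == pytest.approx(
            (0.186 + 0.596) / 2
        )

    def test_generated_occupancies_follow_hill_curve(self):
        series = rf.generate_titration([0.0, 0.1, 2.0], 3, seed=2)
        for c, ts, gt in series:
            holo = rf.hill_fraction(c, 0.186, 0.596, 0.06)
            occ = ts.manifest["occupancies"]
            assert occ[2] == pytest.approx(holo, abs=1e-12)
            # apo/transit split the remainder in the fixed zero-Mg ratio
            assert occ[0] / occ[1] == pytest.approx(0.597 / 0.217, rel=1e-9)
            assert ts.manifest["mg_mM"] == pytest.approx(c)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            rf.generate_titration([-1.0, 0.0, 0.1, 1.0], 2, seed=1)
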